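"""Shrake-Rupley SASA, RSASA references and designability masks."""

import math

import numpy as np
import pytest

from resurf.structure import Atom, Residue, StructureModel
from resurf.sasa import (
    DEFAULT_REFERENCE,
    RsasaReference,
    SasaResult,
    aggregate_monomer_rsasa,
    designable_mask,
    relative_sasa,
    shrake_rupley_sasa,
    surface_mask,
)
from resurf.simulate import extended_peptide_model, toy_reference


def single_atom_model(element="C", radius=1.7):
    return StructureModel(
        chains=["A"],
        residues=[Residue("A", 1, "G", [Atom(element, "CA", [0, 0, 0], radius)])],
    )


def pair_model(r1, r2, d):
    return StructureModel(
        chains=["A"],
        residues=[
            Residue("A", 1, "G", [Atom("C", "A1", [0, 0, 0], r1)]),
            Residue("A", 2, "G", [Atom("C", "A2", [d, 0, 0], r2)]),
        ],
    )


def two_sphere_exact(r1, r2, d, probe):
    """Closed-form SASA of two overlapping probe-expanded spheres:
    full sphere area minus the buried spherical cap."""
    R1, R2 = r1 + probe, r2 + probe

    def accessible(R, other):
        if d >= R + other:
            return 4 * math.pi * R * R
        if d + R <= other:
            return 0.0
        h = R - (d * d + R * R - other * other) / (2 * d)
        return 4 * math.pi * R * R - 2 * math.pi * R * h

    return accessible(R1, R2) + accessible(R2, R1)


class TestShrakeRupley:
    def test_isolated_atom_is_analytic_sphere(self):
        s = shrake_rupley_sasa(single_atom_model(), probe_radius=1.4, n_points=960)
        exact = 4 * math.pi * 3.1**2
        assert s.total == pytest.approx(exact, rel=0.005)

    def test_distant_atoms_are_additive(self):
        far = pair_model(1.7, 1.7, 20.0)
        s = shrake_rupley_sasa(far)
        lone = shrake_rupley_sasa(single_atom_model()).total
        assert s.total == pytest.approx(2 * lone, rel=1e-9)

    @pytest.mark.parametrize("r1,r2,d", [
        (1.7, 1.55, 2.0), (1.7, 1.55, 2.5), (1.7, 1.7, 3.0),
        (1.52, 1.8, 2.2), (1.55, 1.55, 1.8),
    ])
    def test_two_sphere_overlap_matches_closed_form(self, r1, r2, d):
        exact = two_sphere_exact(r1, r2, d, 1.4)
        s = shrake_rupley_sasa(pair_model(r1, r2, d), 1.4, 960)
        assert s.total == pytest.approx(exact, rel=0.01)

    def test_error_shrinks_as_points_double(self):
        configs = [(1.7, 1.55, 2.0), (1.7, 1.55, 2.5), (1.7, 1.7, 3.0),
                   (1.52, 1.8, 2.2), (1.7, 1.52, 2.8), (1.55, 1.55, 1.8)]
        errs = []
        for n in (60, 120, 240, 480, 960, 1920, 3840):
            e = []
            for r1, r2, d in configs:
                exact = two_sphere_exact(r1, r2, d, 1.4)
                got = shrake_rupley_sasa(pair_model(r1, r2, d), 1.4, n).total
                e.append(abs(got - exact) / exact)
            errs.append(np.mean(e))
        # monotone within sampling noise: no doubling may regress much,
        # and the finest grid must beat the coarsest by a wide margin
        for a, b in zip(errs, errs[1:]):
            assert b <= a * 1.3
        assert errs[-1] < errs[0] / 5

    def test_overlapping_identical_atoms_computed_normally(self):
        # degenerate coincident spheres: no crash, non-negative, and the
        # exposed envelope never exceeds two isolated spheres
        s = shrake_rupley_sasa(pair_model(1.7, 1.7, 0.0))
        lone = shrake_rupley_sasa(single_atom_model()).total
        assert np.isfinite(s.total)
        assert 0.0 <= s.total <= 2 * lone + 1e-6

    def test_conservation_atoms_residues_total(self, toy_bundle):
        spec, model, _ = toy_bundle
        s = shrake_rupley_sasa(model, spec.probe_radius, 240)
        assert sum(s.per_residue.values()) == pytest.approx(s.total, abs=1e-6)
        assert s.per_atom.sum() == pytest.approx(s.total, abs=1e-6)
        assert (s.per_atom >= 0).all()

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            shrake_rupley_sasa(single_atom_model(), n_points=31)

    def test_agrees_with_external_oracle_per_residue(self, toy_bundle):
        """Independent cross-check against biotite's SASA implementation
        (Bondi single radii) on the toy assembly, within 2% per residue."""
        import biotite.structure as struc

        spec, model, _ = toy_bundle
        pairs = [(r, a) for r in model.residues for a in r.atoms]
        arr = struc.AtomArray(len(pairs))
        for i, (r, a) in enumerate(pairs):
            arr.coord[i] = a.coords
            arr.chain_id[i] = r.chain_id
            arr.res_id[i] = r.seq_index
            arr.res_name[i] = r.name or "GLY"
            arr.atom_name[i] = a.name
            arr.element[i] = a.element
        ref = struc.sasa(arr, probe_radius=spec.probe_radius,
                         point_number=2000, vdw_radii="Single")
        mine = shrake_rupley_sasa(model, spec.probe_radius, 2000)
        ref_res = {}
        for i, (r, _) in enumerate(pairs):
            key = (r.chain_id, r.seq_index)
            ref_res[key] = ref_res.get(key, 0.0) + float(ref[i])
        for key, area in mine.per_residue.items():
            assert area == pytest.approx(ref_res[key], rel=0.02, abs=0.5)


class TestRelativeSasa:
    def _fake_result(self, area):
        return SasaResult(per_atom=np.array([area]), atoms=[],
                          per_residue={("A", 1): area}, params={})

    def test_half_exposed(self):
        model = single_atom_model()
        model.residues[0].aa = "A"
        ref = RsasaReference({"A": 120.0}, name="test")
        rs = relative_sasa(self._fake_result(60.0), model, ref)
        assert rs[("A", 1)] == pytest.approx(0.5)

    def test_fully_buried_is_zero(self):
        model = single_atom_model()
        model.residues[0].aa = "A"
        ref = RsasaReference({"A": 120.0}, name="test")
        assert relative_sasa(self._fake_result(0.0), model, ref)[("A", 1)] == 0.0

    def test_missing_reference_entry(self):
        model = single_atom_model()
        model.residues[0].aa = "X"
        with pytest.raises(KeyError):
            relative_sasa(self._fake_result(10.0), model, DEFAULT_REFERENCE)

    def test_extended_tripeptide_central_residue_near_one(self):
        """Central Ala of an ideal extended Gly-Ala-Gly should sit at the
        reference maximum (RSASA ~ 1), validating table and geometry
        against each other."""
        gag = extended_peptide_model("GAG")
        s = shrake_rupley_sasa(gag)
        rs = relative_sasa(s, gag, DEFAULT_REFERENCE)
        assert rs[("A", 2)] == pytest.approx(1.0, abs=0.1)


class TestMasks:
    def test_surface_threshold_is_strict(self):
        rs = {1: 0.51, 2: 0.50, 3: 0.49}
        m = surface_mask(rs, threshold=0.5)
        assert m == {1: True, 2: False, 3: False}

    def test_all_buried_globule_has_no_surface(self):
        rs = {i: 0.05 for i in range(1, 21)}
        assert not any(surface_mask(rs).values())

    def test_pipeline_mask_equals_generator_truth(self, toy_bundle, toy_rsasa):
        spec, model, truth = toy_bundle
        mask = designable_mask(
            model, toy_rsasa, spec.active_site_positions,
            rsasa_threshold=spec.rsasa_threshold,
            neighbor_radius=spec.neighbor_radius,
            active_site_radius=spec.active_site_radius,
            interface_cutoff=spec.interface_cutoff,
        )
        for layer in ("surface", "active_site_proximal", "interface", "designable"):
            np.testing.assert_array_equal(
                getattr(mask, layer), getattr(truth, layer), err_msg=layer
            )

    def test_raising_threshold_never_adds_surface(self, toy_bundle, toy_rsasa):
        spec, model, _ = toy_bundle
        prev = None
        for th in (0.1, 0.3, 0.5, 0.7, 0.9):
            mask = designable_mask(model, toy_rsasa, (), rsasa_threshold=th)
            cur = set(mask.surface_positions())
            if prev is not None:
                assert cur.issubset(prev)
            prev = cur

    def test_raising_interface_cutoff_never_adds_designable(self, toy_bundle, toy_rsasa):
        spec, model, _ = toy_bundle
        prev = None
        for cut in (2.0, 4.0, 6.0, 8.0):
            mask = designable_mask(model, toy_rsasa, (), interface_cutoff=cut)
            cur = set(mask.designable_positions())
            if prev is not None:
                assert cur.issubset(prev)
            prev = cur

    def test_active_site_outside_range_rejected(self, toy_bundle, toy_rsasa):
        spec, model, _ = toy_bundle
        with pytest.raises(ValueError):
            designable_mask(model, toy_rsasa, (999,))

    def test_aggregation_uses_most_exposed_copy(self, toy_bundle, toy_rsasa):
        _, model, _ = toy_bundle
        agg = aggregate_monomer_rsasa(toy_rsasa, model, rule="max")
        for pos, v in agg.items():
            copies = [toy_rsasa[(c, pos)] for c in model.chains]
            assert v == max(copies)

    def test_tsv_roundtrip(self, toy_bundle, tmp_path):
        _, _, truth = toy_bundle
        p = tmp_path / "mask.tsv"
        truth.to_tsv(p)
        back = type(truth).from_tsv(p)
        assert back.positions == truth.positions
        np.testing.assert_array_equal(back.designable, truth.designable)
        assert back.annotation_string() == truth.annotation_string()
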