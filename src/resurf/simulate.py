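"""Synthetic data generators for every stage of the re-surfacing pipeline.

Nothing here is fitted to real data; the generators produce inputs with the
*statistical structure* the analysis assumes so the whole pipeline is
testable without downloads:

* toy multimeric assemblies with brute-force-derived surface/interface
  ground truth (stand-in for a crystal-structure homotetramer),
* polyclonal anti-drug-antibody (ADA) ELISA panels whose signal decays
  with the fraction of surface epitopes mutated,
* ordinal 0-4 hypersensitivity score tables coupled to residual binding,
* saturating kinetic progress curves with known maximum velocity.

All generators are seed-deterministic and return provenance metadata
(seed and parameters) alongside the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .structure import Atom, Residue, StructureModel, VDW_RADII
from .sasa import (
    DesignabilityMask,
    RsasaReference,
    sphere_points,
)

__all__ = [
    "ToyAssemblySpec",
    "SyntheticAdaModel",
    "make_toy_tetramer",
    "toy_reference",
    "extended_peptide_model",
    "simulate_ada_panel",
    "simulate_hypersensitivity",
    "simulate_kinetics",
]


# ---------------------------------------------------------------------------
# Toy assemblies

@dataclass
class ToyAssemblySpec:
    """Recipe for a synthetic ring-shaped homo-oligomer.

    Each chain is a compact planar grid of single-carbon pseudo-residues
    (GLY records with one atom), rigid copies arranged in a ring so that
    chain-facing residues form interfaces, outward residues are exposed,
    and grid-interior residues are partially buried.
    """

    n_chains: int = 4
    n_residues: int = 12
    ring_radius: float = 10.0
    grid_spacing: float = 3.8
    jitter: float = 0.3  # Å of deterministic coordinate jitter
    seed: int = 0
    rsasa_threshold: float = 0.5
    neighbor_radius: float = 5.0
    active_site_radius: float = 8.0
    interface_cutoff: float = 5.0
    active_site_positions: tuple[int, ...] = ()
    probe_radius: float = 1.4
    n_points: int = 960

    def __post_init__(self) -> None:
        if self.n_chains < 1 or self.n_residues < 1:
            raise ValueError("need at least one chain and one residue")
        if any(p < 1 or p > self.n_residues for p in self.active_site_positions):
            raise ValueError("active-site positions outside monomer range")


_TOY_RADIUS = VDW_RADII["C"]


def toy_reference(probe_radius: float = 1.4) -> RsasaReference:
    """RSASA reference for single-atom toy residues: the isolated-atom
    accessible area, so a fully exposed toy residue has RSASA 1.0."""
    area = 4.0 * math.pi * (_TOY_RADIUS + probe_radius) ** 2
    return RsasaReference({"G": area}, name="toy-isolated-atom")


def _toy_chain_template(spec: ToyAssemblySpec) -> np.ndarray:
    """Grid of residue centres in the xy plane, centred on the origin."""
    rng = np.random.default_rng(spec.seed)
    n_cols = max(1, int(round(math.sqrt(spec.n_residues))))
    n_rows = math.ceil(spec.n_residues / n_cols)
    pts = []
    for i in range(spec.n_residues):
        r, c = divmod(i, n_cols)
        pts.append([c * spec.grid_spacing, r * spec.grid_spacing, 0.0])
    pts = np.asarray(pts)
    pts -= pts.mean(axis=0)
    pts += rng.normal(0.0, spec.jitter, size=pts.shape)
    return pts


def _rotation_z(theta: float) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _brute_sasa_per_residue(
    coords: np.ndarray, radius: float, probe: float, n_points: int
) -> np.ndarray:
    """Independent O(n^2) Shrake-Rupley for the generator's ground truth
    (plain loops, no spatial index)."""
    unit = sphere_points(n_points)
    n = len(coords)
    rr = radius + probe
    areas = np.zeros(n)
    for i in range(n):
        pts = coords[i] + rr * unit
        accessible = np.ones(n_points, dtype=bool)
        for j in range(n):
            if j == i:
                continue
            if np.linalg.norm(coords[j] - coords[i]) >= 2 * rr:
                continue
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 >= rr * rr
        areas[i] = 4.0 * math.pi * rr * rr * accessible.sum() / n_points
    return areas


def make_toy_tetramer(
    spec: ToyAssemblySpec,
) -> tuple[StructureModel, DesignabilityMask, dict]:
    """Build a toy assembly plus its exact designability ground truth.

    The truth mask is derived at generation time by brute-force geometry —
    all-pairs distances and a direct quadratic-time SASA — fully
    independent of the surface-classification pipeline's spatial indexing,
    so pipeline output can be checked for exact agreement.
    """
    template = _toy_chain_template(spec)
    chain_ids = [chr(ord("A") + i) for i in range(spec.n_chains)]
    coords_by_chain = {}
    residues = []
    for ci, cid in enumerate(chain_ids):
        rot = _rotation_z(2.0 * math.pi * ci / max(spec.n_chains, 1))
        centre = rot @ np.array([spec.ring_radius, 0.0, 0.0])
        coords = template @ rot.T + centre
        coords_by_chain[cid] = coords
        for ri in range(spec.n_residues):
            residues.append(
                Residue(
                    chain_id=cid,
                    seq_index=ri + 1,
                    aa="G",
                    name="GLY",
                    atoms=[
                        Atom(
                            element="C",
                            name="CA",
                            coords=coords[ri],
                            vdw_radius=_TOY_RADIUS,
                        )
                    ],
                )
            )
    model = StructureModel(
        chains=chain_ids, residues=residues,
        assembly_note=f"synthetic {spec.n_chains}-chain toy ring",
    )

    # ---- ground truth by brute force -----------------------------------
    all_coords = np.vstack([coords_by_chain[c] for c in chain_ids])
    sasa = _brute_sasa_per_residue(
        all_coords, _TOY_RADIUS, spec.probe_radius, spec.n_points
    )
    ref_area = 4.0 * math.pi * (_TOY_RADIUS + spec.probe_radius) ** 2
    rsasa = sasa / ref_area  # one atom per residue

    n = spec.n_residues
    # most-exposed chain copy per monomer position
    agg = np.zeros(n)
    for pos in range(n):
        agg[pos] = max(rsasa[ci * n + pos] for ci in range(spec.n_chains))
    surface = agg > spec.rsasa_threshold

    near_surface = surface.copy()
    for ci in range(spec.n_chains):
        coords = coords_by_chain[chain_ids[ci]]
        for p in range(n):
            if near_surface[p]:
                continue
            for q in range(n):
                if surface[q] and np.linalg.norm(coords[p] - coords[q]) <= spec.neighbor_radius:
                    near_surface[p] = True
                    break

    active = np.zeros(n, dtype=bool)
    for ci in range(spec.n_chains):
        coords = coords_by_chain[chain_ids[ci]]
        for p in range(n):
            for a in spec.active_site_positions:
                if np.linalg.norm(coords[p] - coords[a - 1]) <= spec.active_site_radius:
                    active[p] = True

    interface = np.zeros(n, dtype=bool)
    if spec.n_chains >= 2:
        for ci, cid in enumerate(chain_ids):
            own = coords_by_chain[cid]
            others = np.vstack(
                [coords_by_chain[c] for c in chain_ids if c != cid]
            )
            for p in range(n):
                dmin = min(
                    np.linalg.norm(own[p] - o) for o in others
                )
                if dmin < spec.interface_cutoff:
                    interface[p] = True

    truth = DesignabilityMask(
        positions=list(range(1, n + 1)),
        surface=surface,
        active_site_proximal=active,
        interface=interface,
        designable=near_surface & ~active & ~interface,
        params={
            "rsasa_threshold": spec.rsasa_threshold,
            "neighbor_radius": spec.neighbor_radius,
            "active_site_radius": spec.active_site_radius,
            "interface_cutoff": spec.interface_cutoff,
            "aggregation": "max",
            "active_site_positions": list(spec.active_site_positions),
        },
    )
    meta = {"generator": "make_toy_tetramer", **asdict(spec)}
    return model, truth, meta


# ---------------------------------------------------------------------------
# Ideal-geometry extended peptides (reference-construction fixture)

_BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231, "CA-CB": 1.521}
_ANGLE = {"N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7,
          "CA-C-O": 120.8, "N-CA-CB": 110.4}


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension (NeRF) placement of atom D given A-B-C."""
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [-bond * math.cos(ang),
         bond * math.sin(ang) * math.cos(tor),
         bond * math.sin(ang) * math.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def extended_peptide_model(sequence: str) -> StructureModel:
    """Ideal fully-extended (phi = psi = omega = 180°) backbone model.

    Atoms: N, CA, C, O per residue plus CB for every residue except
    glycine; side chains beyond CB are not built, so this is intended for
    Gly-X-Gly style reference fixtures with small X (it is a synthetic
    construction, not a parsed structure).
    """
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    coords: list[dict[str, np.ndarray]] = []
    for i, aa in enumerate(seq):
        res: dict[str, np.ndarray] = {}
        if i == 0:
            res["N"] = np.zeros(3)
            res["CA"] = np.array([_BOND["N-CA"], 0.0, 0.0])
            ang = math.radians(180.0 - _ANGLE["N-CA-C"])
            res["C"] = res["CA"] + _BOND["CA-C"] * np.array(
                [math.cos(ang), math.sin(ang), 0.0]
            )
        else:
            prev = coords[i - 1]
            res["N"] = _place(prev["N"], prev["CA"], prev["C"],
                              _BOND["C-N"], _ANGLE["CA-C-N"], 180.0)  # psi
            res["CA"] = _place(prev["CA"], prev["C"], res["N"],
                               _BOND["N-CA"], _ANGLE["C-N-CA"], 180.0)  # omega
            res["C"] = _place(prev["C"], res["N"], res["CA"],
                              _BOND["CA-C"], _ANGLE["N-CA-C"], 180.0)  # phi
        coords.append(res)
    # carbonyl O and CB once all backbone frames exist
    for i, aa in enumerate(seq):
        res = coords[i]
        if i + 1 < len(seq):
            nxt = coords[i + 1]["N"]
            res["O"] = _place(nxt, res["CA"], res["C"],
                              _BOND["C-O"], _ANGLE["CA-C-O"], 180.0)
        else:
            res["O"] = _place(res["N"], res["CA"], res["C"],
                              _BOND["C-O"], _ANGLE["CA-C-O"], 0.0)
        if aa != "G":
            u1 = res["N"] - res["CA"]
            u1 /= np.linalg.norm(u1)
            u2 = res["C"] - res["CA"]
            u2 /= np.linalg.norm(u2)
            c12 = float(u1 @ u2)
            target = math.cos(math.radians(_ANGLE["N-CA-CB"]))
            a = target / (1.0 + c12)
            s = u1 + u2
            norm = np.cross(u1, u2)
            norm /= np.linalg.norm(norm)
            b = math.sqrt(max(0.0, 1.0 - a * a * float(s @ s)))
            res["CB"] = res["CA"] + _BOND["CA-CB"] * (a * s + b * norm)

    from .structure import _ONE_TO_THREE

    residues = []
    for i, aa in enumerate(seq):
        atoms = []
        for name, xyz in coords[i].items():
            el = name[0]
            atoms.append(Atom(element=el, name=name, coords=xyz,
                              vdw_radius=VDW_RADII[el]))
        residues.append(Residue(chain_id="A", seq_index=i + 1, aa=aa,
                                name=_ONE_TO_THREE.get(aa, "UNK"), atoms=atoms))
    return StructureModel(chains=["A"], residues=residues,
                          assembly_note="synthetic ideal extended peptide")


# ---------------------------------------------------------------------------
# Polyclonal ADA ELISA panels

@dataclass
class SyntheticAdaModel:
    """Ground-truth polyclonal ADA model behind the simulated ELISA.

    A repertoire of ``n_clones`` antibody clones each recognises a small
    set of surface positions (its epitope).  A variant evades a clone when
    at least one of the clone's epitope positions is mutated
    (all-or-nothing rule; ``graded_affinity`` switches to a per-hit
    attenuation instead).  The plate signal follows a four-parameter
    logistic in dilution with the top scaled by the fraction of clones
    retained, plus multiplicative lognormal read noise and an additive
    plate background.
    """

    surface_positions: Sequence[int]
    n_clones: int = 20
    epitope_size: int = 3
    top: float = 3.0
    bottom: float = 0.02
    ec50: float = 3.0e4  # fold dilution at half-maximal signal
    hill: float = 1.0
    noise_sigma: float = 0.1  # lognormal sigma of multiplicative read noise
    background: float = 0.05  # additive secondary-only plate background
    epitope_effect: float = 1.0  # 0 => mutations never evade clones
    graded_affinity: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.top > self.bottom >= 0):
            raise ValueError("need top > bottom >= 0")
        if self.hill <= 0:
            raise ValueError("hill must be positive")
        if self.epitope_size > len(self.surface_positions):
            raise ValueError("epitope_size exceeds surface position count")

    def draw_epitopes(self, rng: np.random.Generator) -> list[frozenset[int]]:
        surf = np.asarray(sorted(self.surface_positions))
        return [
            frozenset(rng.choice(surf, size=self.epitope_size, replace=False).tolist())
            for _ in range(self.n_clones)
        ]

    def retained_fraction(
        self, mutated: set[int], epitopes: Sequence[frozenset[int]]
    ) -> float:
        """Fraction of the clonal signal a variant retains."""
        weights = []
        for epi in epitopes:
            hits = len(epi & mutated)
            if self.graded_affinity:
                w = (1.0 - 0.6) ** hits  # each hit attenuates the clone
            else:
                w = 0.0 if hits >= 1 else 1.0
            weights.append(w)
        f = float(np.mean(weights))
        return 1.0 - self.epitope_effect * (1.0 - f)


DEFAULT_DILUTIONS = (300.0, 1.2e3, 4.8e3, 1.92e4, 7.68e4, 3.072e5, 1.2288e6)


def simulate_ada_panel(
    model: SyntheticAdaModel,
    variants: Mapping[str, set[int]],
    dilutions: Sequence[float] = DEFAULT_DILUTIONS,
    n_replicates: int = 3,
    plate_id: str = "P1",
    sample_id: str = "pooled_ada",
) -> tuple[pd.DataFrame, dict]:
    """Simulate an ADA ELISA plate for a panel of variant antigens.

    ``variants`` maps antigen id to the set of mutated surface positions
    (the wild type is the empty set).  Each antigen gets experimental
    wells across the dilution grid in technical replicates, plus
    secondary-only background wells and a healthy-control series.
    Deterministic for a fixed model seed.
    """
    if len(dilutions) == 0:
        raise ValueError("empty dilution series")
    bad = {a: m - set(model.surface_positions) for a, m in variants.items()
           if m - set(model.surface_positions)}
    if bad:
        raise ValueError(f"mutations outside surface positions: {bad}")

    rng = np.random.default_rng(model.seed)
    epitopes = model.draw_epitopes(rng)
    rows = []

    def noise() -> float:
        if model.noise_sigma == 0:
            return 1.0
        return float(rng.lognormal(0.0, model.noise_sigma))

    retained = {}
    for antigen, mutated in variants.items():
        f = model.retained_fraction(set(mutated), epitopes)
        retained[antigen] = f
        top_v = model.bottom + (model.top - model.bottom) * f
        for d in dilutions:
            curve = model.bottom + (top_v - model.bottom) / (
                1.0 + (d / model.ec50) ** model.hill
            )
            for rep in range(1, n_replicates + 1):
                rows.append({
                    "plate_id": plate_id, "sample_id": sample_id,
                    "antigen_id": antigen, "dilution": d, "replicate": rep,
                    "role": "experimental",
                    "od450": model.background + curve * noise(),
                })
        # healthy-control series for the same antigen (no specific ADA)
        for d in dilutions:
            for rep in range(1, n_replicates + 1):
                rows.append({
                    "plate_id": plate_id, "sample_id": "healthy_pool",
                    "antigen_id": antigen, "dilution": d, "replicate": rep,
                    "role": "healthy_control",
                    "od450": model.background + model.bottom * noise(),
                })
    for rep in range(1, n_replicates + 1):
        rows.append({
            "plate_id": plate_id, "sample_id": "none", "antigen_id": "none",
            "dilution": 1.0, "replicate": rep, "role": "secondary_only",
            "od450": model.background * noise(),
        })

    meta = {
        "generator": "simulate_ada_panel",
        "seed": model.seed,
        "params": {k: v for k, v in asdict(model).items() if k != "surface_positions"},
        "retained_fraction": retained,
        "dilutions": list(dilutions),
    }
    return pd.DataFrame(rows), meta


# ---------------------------------------------------------------------------
# Hypersensitivity scores

SENSITIZATION_DAYS = (0, 7, 14)
CHALLENGE_DAYS = (21, 28, 35)


def simulate_hypersensitivity(
    groups: Mapping[str, float],
    n_mice: Mapping[str, int] | int,
    seed: int = 0,
    amplitude: float = 3.2,
    noise_sd: float = 0.45,
    thresholds: Sequence[float] = (0.5, 1.5, 2.5, 3.5),
    sensitization_ramp: Sequence[float] = (0.0, 0.5, 1.0),
) -> tuple[pd.DataFrame, dict]:
    """Ordinal 0-4 hypersensitivity scores for a sensitise-then-challenge
    design.

    All arms are sensitised with the wild-type antigen (binding level 1)
    on the sensitisation days with a ramping response, and the model
    forces full penetrance (score >= 1 for every mouse) at the final
    sensitisation dose.  On challenge days each arm's latent severity is
    ``amplitude * level + noise`` cut at fixed thresholds into {0..4},
    where ``level`` is the arm's residual binding (vehicle 0, wild type 1).
    """
    if isinstance(n_mice, int):
        n_mice = {g: n_mice for g in groups}
    for g, n in n_mice.items():
        if n < 1:
            raise ValueError(f"arm {g!r}: need n >= 1")
    unknown = set(n_mice) - set(groups)
    if unknown:
        raise ValueError(f"unknown arms {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    th = np.asarray(thresholds, dtype=float)
    rows = []
    for group in groups:
        level = groups[group]
        for m in range(1, n_mice[group] + 1):
            mouse = f"{group}_{m:02d}"
            for day, ramp in zip(SENSITIZATION_DAYS, sensitization_ramp):
                latent = amplitude * 1.0 * ramp + rng.normal(0.0, noise_sd)
                score = int(np.digitize(latent, th))
                if day == SENSITIZATION_DAYS[-1]:
                    score = max(score, 1)  # forced penetrance after dose 3
                rows.append({"mouse_id": mouse, "group": group,
                             "day": day, "score": score})
            for day in CHALLENGE_DAYS:
                latent = amplitude * level + rng.normal(0.0, noise_sd)
                rows.append({"mouse_id": mouse, "group": group, "day": day,
                             "score": int(np.digitize(latent, th))})
    meta = {
        "generator": "simulate_hypersensitivity", "seed": seed,
        "groups": dict(groups), "n_mice": dict(n_mice),
        "amplitude": amplitude, "noise_sd": noise_sd,
        "thresholds": list(thresholds),
    }
    return pd.DataFrame(rows), meta


# ---------------------------------------------------------------------------
# Kinetic progress curves

def simulate_kinetics(
    true_vmax: Mapping[str, float],
    n_timepoints: int = 121,
    interval: float = 2.0,  # minutes
    noise_sd: float = 0.0,
    seed: int = 0,
    saturation_level: float | None = 1000.0,
) -> tuple[pd.DataFrame, dict]:
    """Fluorescence progress curves with known initial velocity.

    Signal follows F(t) = Fmax (1 − exp(−v t / Fmax)), whose initial
    slope is exactly v; ``saturation_level=None`` gives a pure linear
    phase.  Additive Gaussian read noise; deterministic per seed.
    """
    if n_timepoints < 4:
        raise ValueError("need at least 4 timepoints")
    if any(v < 0 for v in true_vmax.values()):
        raise ValueError("vmax must be non-negative")
    rng = np.random.default_rng(seed)
    t = np.arange(n_timepoints) * interval
    rows = []
    for well, v in true_vmax.items():
        if saturation_level is None or v == 0:
            f = v * t
        else:
            f = saturation_level * (1.0 - np.exp(-v * t / saturation_level))
        if noise_sd > 0:
            f = f + rng.normal(0.0, noise_sd, size=f.shape)
        for ti, fi in zip(t, f):
            rows.append({"well": well, "time_min": float(ti), "signal": float(fi)})
    meta = {
        "generator": "simulate_kinetics", "seed": seed,
        "true_vmax": dict(true_vmax), "n_timepoints": n_timepoints,
        "interval": interval, "noise_sd": noise_sd,
        "saturation_level": saturation_level,
    }
    return pd.DataFrame(rows), meta
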