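"""Synthetic inputs for the pipeline: toy 3D structures and planted-rule
feature tables.

``make_structure`` builds polypeptides from ideal backbone geometry
(standard bond lengths/angles, geometry-specific phi/psi) with Ala-like
C-beta stubs; it covers the structural stages (SASA, secondary structure,
descriptors) without any database access. ``make_planted_table`` builds
feature tables whose class labels follow a known conjunction of one-sided
thresholds plus label noise — the statistical structure the classification
and interpretation stages are meant to recover.

Full side-chain rotamers are deliberately out of scope: surface-composition
logic depends on residue identity and backbone burial, which stubs capture.
Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structure_io import (
    Atom,
    DEFAULT_RADII,
    ONE_TO_THREE,
    Residue,
    Structure,
)
from .secondary_structure import kabsch_sander_energy, HBOND_CUTOFF

__all__ = [
    "StructureSpec",
    "PlantedRule",
    "PlantedTableSpec",
    "make_structure",
    "make_antiparallel_sheet",
    "make_planted_table",
    "AA_THREE",
]

AA_THREE = sorted(ONE_TO_THREE.values())

# ideal backbone internal coordinates (Å, degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.229, 1.530
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.5
_OMEGA = 180.0

_DIHEDRALS = {
    "helix": (-57.0, -47.0),
    "strand": (-139.0, 135.0),
    "extended": (-180.0, 180.0),
}


class SequenceError(ValueError):
    """Sequence contains letters outside the 20 standard amino acids."""


@dataclass(frozen=True)
class StructureSpec:
    """Recipe for one toy polypeptide.

    sequence : one-letter amino-acid string.
    geometry : helix | strand | extended | coil-perturbed.
    perturbation_sd : isotropic Gaussian coordinate noise, Å.
    seed : RNG seed (used for coil dihedrals and coordinate noise).
    """

    sequence: str
    geometry: str = "helix"
    perturbation_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        bad = set(self.sequence.upper()) - set(ONE_TO_THREE)
        if bad or not self.sequence:
            raise SequenceError(f"invalid sequence letters: {sorted(bad)}")
        if self.perturbation_sd < 0:
            raise ValueError("perturbation_sd must be >= 0")
        if self.geometry not in ("helix", "strand", "extended", "coil-perturbed"):
            raise ValueError(f"unknown geometry {self.geometry!r}")


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Natural-extension-reference-frame placement of atom D from A-B-C."""
    theta = np.deg2rad(angle_deg)
    chi = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(chi), np.sin(theta) * np.sin(chi)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _cb_position(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ala-like C-beta stub: ~110.5 deg to both N and C, out of the backbone
    plane (one consistent side for the whole chain)."""
    u = (n - ca) / np.linalg.norm(n - ca)
    v = (c - ca) / np.linalg.norm(c - ca)
    cos_t = np.cos(np.deg2rad(110.5))
    a = cos_t / (1.0 + float(u @ v))
    w = np.cross(u, v)
    b2 = 1.0 - a * a * float((u + v) @ (u + v))
    b = np.sqrt(max(b2, 0.0)) / np.linalg.norm(w)
    d = a * (u + v) + b * w
    return ca + _B_CA_CB * d / np.linalg.norm(d)


def make_structure(spec: StructureSpec) -> Structure:
    """Build the Structure for a :class:`StructureSpec`. Deterministic per
    (sequence, geometry, perturbation_sd, seed)."""
    seq = spec.sequence.upper()
    n_res = len(seq)
    rng = np.random.default_rng(spec.seed)

    if spec.geometry == "coil-perturbed":
        # loose polyproline-II-ish coil region, varied per residue
        phis = rng.uniform(-150.0, -60.0, n_res)
        psis = rng.uniform(-50.0, 160.0, n_res)
    else:
        phi, psi = _DIHEDRALS[spec.geometry]
        phis = np.full(n_res, phi)
        psis = np.full(n_res, psi)

    N = np.empty((n_res, 3))
    CA = np.empty((n_res, 3))
    C = np.empty((n_res, 3))
    # first residue seeds the frame
    N[0] = np.array([0.0, 0.0, 0.0])
    CA[0] = np.array([_B_N_CA, 0.0, 0.0])
    ang = np.deg2rad(_A_N_CA_C)
    C[0] = CA[0] + _B_CA_C * np.array([np.cos(np.pi - ang), np.sin(np.pi - ang), 0.0])
    for i in range(1, n_res):
        N[i] = _place(N[i - 1], CA[i - 1], C[i - 1], _B_C_N, _A_CA_C_N, psis[i - 1])
        CA[i] = _place(CA[i - 1], C[i - 1], N[i], _B_N_CA, _A_C_N_CA, _OMEGA)
        C[i] = _place(C[i - 1], N[i], CA[i], _B_CA_C, _A_N_CA_C, phis[i])

    O = np.empty((n_res, 3))
    for i in range(n_res):
        # carbonyl O trans to the next amide N (dihedral psi + 180)
        O[i] = _place(N[i], CA[i], C[i], _B_C_O, _A_CA_C_O, psis[i] + 180.0)

    residues: list[Residue] = []
    for i, letter in enumerate(seq):
        three = ONE_TO_THREE[letter]
        atoms = [
            Atom("N", "N", N[i], DEFAULT_RADII["N"], 90.0),
            Atom("CA", "C", CA[i], DEFAULT_RADII["C"], 90.0),
            Atom("C", "C", C[i], DEFAULT_RADII["C"], 90.0),
            Atom("O", "O", O[i], DEFAULT_RADII["O"], 90.0),
        ]
        if three != "GLY":
            atoms.append(Atom("CB", "C", _cb_position(N[i], CA[i], C[i]),
                              DEFAULT_RADII["C"], 90.0))
        residues.append(Residue(index=i, three_letter=three, atoms=atoms))

    if spec.perturbation_sd > 0:
        for r in residues:
            for a in r.atoms:
                a.coords = a.coords + rng.normal(0.0, spec.perturbation_sd, 3)

    pid = f"synth_{spec.geometry}_{spec.seed}_{seq[:8]}"
    return Structure(protein_id=pid, chains={"A": residues})


def _transform(residues: list[Residue], R: np.ndarray, t: np.ndarray) -> list[Residue]:
    out = []
    for r in residues:
        atoms = [Atom(a.name, a.element, R @ a.coords + t, a.radius, a.confidence)
                 for a in r.atoms]
        out.append(Residue(index=r.index, three_letter=r.three_letter, atoms=atoms))
    return out


def _count_interchain_hbonds(res_a: list[Residue], res_b: list[Residue]) -> tuple[int, float]:
    """Kabsch–Sander bonds between two strands (both donor directions)."""

    def frames(residues: list[Residue]):
        rows = []
        for r in residues:
            n, ca, c, o = (r.atom(x).coords for x in ("N", "CA", "C", "O"))
            rows.append((n, ca, c, o))
        return rows

    fa, fb = frames(res_a), frames(res_b)

    def h_pos(frames_list, i):
        if i == 0:
            return None
        n = frames_list[i][0]
        c_prev, o_prev = frames_list[i - 1][2], frames_list[i - 1][3]
        d = c_prev - o_prev
        return n + d / np.linalg.norm(d)

    count, total = 0, 0.0
    for donor_frames, acc_frames in ((fa, fb), (fb, fa)):
        for i in range(len(donor_frames)):
            h = h_pos(donor_frames, i)
            if h is None:
                continue
            for j in range(len(acc_frames)):
                e = kabsch_sander_energy(donor_frames[i][0], h,
                                         acc_frames[j][2], acc_frames[j][3])
                if e < HBOND_CUTOFF:
                    count += 1
                    total += e
    return count, total


def make_antiparallel_sheet(sequence: str, seed: int = 0) -> Structure:
    """Two ideal strands paired antiparallel into a two-chain sheet.

    The second strand is the first rotated 180 degrees about the axis
    perpendicular to the sheet plane; its rigid placement is chosen by a
    deterministic grid search maximizing the number (then total energy) of
    inter-strand Kabsch–Sander hydrogen bonds.
    """
    strand = make_structure(StructureSpec(sequence, "strand", 0.0, seed))
    res_a = strand.chains["A"]

    # align the strand axis (first CA -> last CA) with +x, centroid at origin
    ca = np.array([r.atom("CA").coords for r in res_a])
    axis = ca[-1] - ca[0]
    axis /= np.linalg.norm(axis)
    x = np.array([1.0, 0.0, 0.0])
    v = np.cross(axis, x)
    s, c = np.linalg.norm(v), float(axis @ x)
    if s < 1e-12:
        R_align = np.eye(3)
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R_align = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
    centroid = ca.mean(axis=0)
    res_a = _transform(res_a, R_align, -R_align @ centroid)

    rz = np.diag([-1.0, -1.0, 1.0])  # 180 deg about z
    best = None
    coarse = [
        (dx, dy, dz)
        for dx in np.arange(-3.5, 3.51, 0.5)
        for dy in np.arange(3.6, 6.01, 0.3)
        for dz in np.arange(-1.0, 1.01, 0.5)
    ]
    for stage_offsets in (coarse, None):
        if stage_offsets is None:  # refine around the coarse optimum
            bx, by, bz = best[2]
            stage_offsets = [
                (bx + ddx, by + ddy, bz + ddz)
                for ddx in np.arange(-0.4, 0.41, 0.1)
                for ddy in np.arange(-0.25, 0.26, 0.05)
                for ddz in np.arange(-0.4, 0.41, 0.1)
            ]
        for dx, dy, dz in stage_offsets:
            cand = _transform(res_a, rz, np.array([dx, dy, dz]))
            n_hb, e_tot = _count_interchain_hbonds(res_a, cand)
            if best is None or (n_hb, -e_tot) > (best[0], best[1]):
                best = (n_hb, -e_tot, (dx, dy, dz), cand)
    res_b = best[3]
    return Structure(
        protein_id=f"synth_sheet_{seed}_{sequence[:8]}",
        chains={"A": res_a, "B": res_b},
    )


@dataclass(frozen=True)
class PlantedRule:
    """One-sided threshold: the secreted class satisfies
    ``feature direction boundary`` (direction '<' or '>')."""

    feature: str
    direction: str
    boundary: float

    def __post_init__(self) -> None:
        if self.direction not in ("<", ">"):
            raise ValueError("direction must be '<' or '>'")
        if not 0 < self.boundary < 100:
            raise ValueError("boundary must be in (0, 100)")

    def satisfied(self, value: np.ndarray) -> np.ndarray:
        return value < self.boundary if self.direction == "<" else value > self.boundary


@dataclass(frozen=True)
class PlantedTableSpec:
    """Recipe for a planted-threshold feature table.

    The secreted class is the conjunction of all rules; labels are flipped
    with probability ``noise_rate``; ``n_noise_features`` class-independent
    uniform columns are appended; ``compositional_block`` adds 20
    simplex-distributed amino-acid composition columns summing to 100.
    """

    n_per_class: int = 400
    rules: tuple[PlantedRule, ...] = (
        PlantedRule("surf_GLU_pct", "<", 9.0),
        PlantedRule("surf_CYS_pct", ">", 1.8),
        PlantedRule("surf_LEU_pct", ">", 5.8),
    )
    noise_rate: float = 0.05
    n_noise_features: int = 10
    compositional_block: bool = False
    window: float = 5.0  # half-width of the uniform band around each boundary
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.noise_rate < 0.5:
            raise ValueError("noise_rate must be in [0, 0.5)")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        feats = {}
        for r in self.rules:
            feats.setdefault(r.feature, []).append(r)
        for feat, rs in feats.items():
            lo = max((r.boundary for r in rs if r.direction == ">"), default=0.0)
            hi = min((r.boundary for r in rs if r.direction == "<"), default=100.0)
            if lo >= hi:
                raise ValueError(f"contradictory rules on {feat}: empty secreted region")


def make_planted_table(spec: PlantedTableSpec) -> pd.DataFrame:
    """Generate the feature table for a :class:`PlantedTableSpec`.

    Rule features are sampled uniformly in a band around each boundary and
    rows are accepted into the class matching the rule conjunction, so the
    two classes differ exactly by the planted rules before label flips.
    Returns a DataFrame with a ``class`` column in {'secreted', 'cytosol'}.
    """
    rng = np.random.default_rng(spec.seed)
    rule_feats = list(dict.fromkeys(r.feature for r in spec.rules))

    def draw(n: int) -> pd.DataFrame:
        cols = {}
        for feat in rule_feats:
            bounds = [r.boundary for r in spec.rules if r.feature == feat]
            lo = max(0.0, min(bounds) - spec.window)
            hi = min(100.0, max(bounds) + spec.window)
            cols[feat] = rng.uniform(lo, hi, n)
        return pd.DataFrame(cols)

    want = {"secreted": spec.n_per_class, "cytosol": spec.n_per_class}
    pools = {"secreted": [], "cytosol": []}
    guard = 0
    while any(sum(len(p) for p in pools[c]) < want[c] for c in want):
        guard += 1
        if guard > 10_000:
            raise RuntimeError("rejection sampling failed to fill both classes")
        batch = draw(4 * spec.n_per_class)
        sat = np.ones(len(batch), dtype=bool)
        for r in spec.rules:
            sat &= r.satisfied(batch[r.feature].to_numpy())
        for cls, m in (("secreted", sat), ("cytosol", ~sat)):
            need = want[cls] - sum(len(p) for p in pools[cls])
            if need > 0:
                pools[cls].append(batch[m].head(need))

    frames = []
    for cls in ("secreted", "cytosol"):
        f = pd.concat(pools[cls], ignore_index=True)
        f["class"] = cls
        frames.append(f)
    table = pd.concat(frames, ignore_index=True)

    # label noise: flip each row's label with probability noise_rate
    flip = rng.random(len(table)) < spec.noise_rate
    swapped = table["class"].map({"secreted": "cytosol", "cytosol": "secreted"})
    table.loc[flip, "class"] = swapped[flip]

    for k in range(spec.n_noise_features):
        table.insert(
            len(table.columns) - 1, f"noise_{k:02d}", rng.uniform(0.0, 20.0, len(table))
        )

    if spec.compositional_block:
        comp = rng.dirichlet(np.full(20, 5.0), len(table)) * 100.0
        for j, aa in enumerate(AA_THREE):
            name = f"comp_{aa}_pct"
            table.insert(len(table.columns) - 1, name, comp[:, j])

    table.index = [f"prot_{i:04d}" for i in range(len(table))]
    table.index.name = "protein_id"
    # shuffle row order so classes are interleaved (deterministic)
    order = rng.permutation(len(table))
    return table.iloc[order]
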