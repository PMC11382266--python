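"""Per-protein surface-chemistry descriptors, feature tables, correlation
pruning and group-comparison reports.

The default registry has 34 descriptors, all in percent units:

* 20 surface amino-acid compositions (over surface residues; sum to 100);
* 5 residue-class compositions over the surface — hydrophilic, hydrophobic,
  positively charged, negatively charged, polar uncharged; Gly, Pro and Cys
  belong to none of the four chemistry classes, so these need not sum to 100
  (hydrophilic = positive + negative + polar-uncharged by definition);
* surface and overall alpha-helix / beta-sheet compositions;
* the ratio of surface residues to all residues;
* 4 side-chain functional-group compositions over the surface (amide,
  hydroxyl, carboxyl/carboxylate, thiol bearers).

The registry is a documented reconstruction of a plausible descriptor set
for this kind of surface analysis and is configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .secondary_structure import (
    UndefinedCompositionError,
    assign_ss,
    ss_composition,
)
from .structure_io import Structure
from .surface_sasa import SasaParams, SurfaceProfile, surface_profile
from .synthetic_data import AA_THREE

__all__ = [
    "RESIDUE_CLASSES",
    "FUNCTIONAL_GROUPS",
    "DEFAULT_REGISTRY",
    "descriptor_vector",
    "build_feature_table",
    "prune_correlated",
    "group_report",
    "DuplicateRowError",
    "NoComparisonError",
]

#: Chemistry-based residue classes. The four charge/polarity classes omit
#: Gly, Pro and Cys; hydrophilic is the union of the first three.
RESIDUE_CLASSES: dict[str, frozenset[str]] = {
    "positive": frozenset({"ARG", "HIS", "LYS"}),
    "negative": frozenset({"ASP", "GLU"}),
    "polar_uncharged": frozenset({"SER", "THR", "ASN", "GLN"}),
    "hydrophobic": frozenset({"ALA", "ILE", "LEU", "MET", "PHE", "TRP", "TYR", "VAL"}),
}
RESIDUE_CLASSES["hydrophilic"] = (
    RESIDUE_CLASSES["positive"]
    | RESIDUE_CLASSES["negative"]
    | RESIDUE_CLASSES["polar_uncharged"]
)

#: Side-chain functional-group bearers.
FUNCTIONAL_GROUPS: dict[str, frozenset[str]] = {
    "amide": frozenset({"ASN", "GLN"}),
    "hydroxyl": frozenset({"SER", "THR", "TYR"}),
    "carboxyl": frozenset({"ASP", "GLU"}),
    "thiol": frozenset({"CYS"}),
}

DEFAULT_REGISTRY: tuple[str, ...] = tuple(
    [f"surf_{aa}_pct" for aa in AA_THREE]
    + [f"surf_{cls}_pct" for cls in
       ("hydrophilic", "hydrophobic", "positive", "negative", "polar_uncharged")]
    + ["surf_helix_pct", "surf_sheet_pct", "overall_helix_pct", "overall_sheet_pct",
       "surface_ratio_pct"]
    + [f"surf_{grp}_pct" for grp in ("amide", "hydroxyl", "carboxyl", "thiol")]
)


class DuplicateRowError(ValueError):
    """Two inputs share a protein_id."""


class NoComparisonError(ValueError):
    """group_report needs at least two classes with enough rows."""


def descriptor_vector(
    s: Structure,
    prof: SurfaceProfile,
    ss: dict[tuple[str, int], str],
    registry: tuple[str, ...] = DEFAULT_REGISTRY,
) -> pd.Series:
    """The named descriptor values (percent) for one protein.

    Surface compositions are over surface residues only; overall quantities
    over all residues. Raises :class:`UndefinedCompositionError` when the
    structure has no surface residues.
    """
    residues = [(r.chain, r.index, r.three_letter) for r in prof.residues]
    surface = [r for r, flag in zip(residues, prof.surface_mask) if flag]
    if not surface:
        raise UndefinedCompositionError(f"{s.protein_id}: no surface residues")

    surf_codes = [three for _, _, three in surface]
    n_surf, n_all = len(surf_codes), len(residues)

    values: dict[str, float] = {}
    for aa in AA_THREE:
        values[f"surf_{aa}_pct"] = 100.0 * surf_codes.count(aa) / n_surf
    for cls, members in RESIDUE_CLASSES.items():
        values[f"surf_{cls}_pct"] = (
            100.0 * sum(1 for c in surf_codes if c in members) / n_surf
        )
    for grp, members in FUNCTIONAL_GROUPS.items():
        values[f"surf_{grp}_pct"] = (
            100.0 * sum(1 for c in surf_codes if c in members) / n_surf
        )

    labels = [ss[(chain, idx)] for chain, idx, _ in residues]
    overall = ss_composition(labels)
    surf_ss = ss_composition(labels, mask=prof.surface_mask)
    values["overall_helix_pct"] = overall["H"]
    values["overall_sheet_pct"] = overall["E"]
    values["surf_helix_pct"] = surf_ss["H"]
    values["surf_sheet_pct"] = surf_ss["E"]
    values["surface_ratio_pct"] = 100.0 * n_surf / n_all

    missing = [name for name in registry if name not in values]
    if missing:
        raise KeyError(f"registry names not computable: {missing}")
    return pd.Series({name: values[name] for name in registry}, name=s.protein_id)


def build_feature_table(
    inputs: list[tuple[Structure, str]],
    params: SasaParams | None = None,
    registry: tuple[str, ...] = DEFAULT_REGISTRY,
) -> pd.DataFrame:
    """One descriptor row per (Structure, label) input plus a ``class``
    column. Deterministic; duplicate protein ids are an error."""
    if not inputs:
        raise ValueError("need at least one (Structure, label) input")
    params = params or SasaParams()
    rows, labels, ids = [], [], []
    for s, label in inputs:
        if s.protein_id in ids:
            raise DuplicateRowError(f"duplicate protein_id {s.protein_id!r}")
        prof = surface_profile(s, params)
        ss = assign_ss(s)
        rows.append(descriptor_vector(s, prof, ss, registry))
        labels.append(label)
        ids.append(s.protein_id)
    table = pd.DataFrame(rows)
    table.index.name = "protein_id"
    table["class"] = labels
    return table


def feature_columns(t: pd.DataFrame, label_col: str = "class") -> list[str]:
    return [c for c in t.columns if c != label_col]


def prune_correlated(
    t: pd.DataFrame,
    threshold: float = 0.85,
    label_col: str = "class",
) -> tuple[pd.DataFrame, list[str]]:
    """Drop one member of every feature pair with |Pearson r| strictly above
    ``threshold``.

    Pairs are processed in descending |r| order (ties broken by column
    name); within a pair the member with the larger cumulative |r| against
    all other features is removed; pairs whose members were already removed
    are skipped. Zero-variance columns are removed up front with a warning
    (their correlation is undefined). The label column is untouched.
    """
    feats = feature_columns(t, label_col)
    if len(feats) < 2 or len(t) < 3:
        raise ValueError("need >= 2 feature columns and >= 3 rows")

    removed: list[str] = []
    X = t[feats]
    constant = [c for c in feats if np.isclose(X[c].std(ddof=0), 0.0)]
    if constant:
        warnings.warn(
            f"removing zero-variance columns (correlation undefined): {constant}"
        )
        removed.extend(constant)
        feats = [c for c in feats if c not in constant]
        X = t[feats]

    corr = X.corr(method="pearson").abs()
    np.fill_diagonal(corr.values, 0.0)
    cumulative = corr.sum(axis=0)

    pairs = [
        (corr.iat[i, j], feats[i], feats[j])
        for i in range(len(feats))
        for j in range(i + 1, len(feats))
        if corr.iat[i, j] > threshold
    ]
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))

    dropped: set[str] = set()
    for _, a, b in pairs:
        if a in dropped or b in dropped:
            continue
        ca, cb = cumulative[a], cumulative[b]
        if ca > cb:
            victim = a
        elif cb > ca:
            victim = b
        else:
            victim = max(a, b)  # deterministic tie-break
        dropped.add(victim)
        removed.append(victim)

    keep = [c for c in t.columns if c not in set(removed)]
    return t[keep].copy(), removed


@dataclass
class GroupReport:
    """Per-class comparison of one descriptor (shared-bin histograms,
    means/SDs, Mann–Whitney U p-value; degenerate constant data gives p=1)."""

    descriptor: str
    bins: np.ndarray
    counts: dict[str, np.ndarray]
    means: dict[str, float]
    sds: dict[str, float]
    p_values: dict[tuple[str, str], float]
    test: str = "mann-whitney-u"


def group_report(
    t: pd.DataFrame,
    descriptor: str,
    by_label: str = "class",
    n_bins: int = 20,
) -> GroupReport:
    """Compare a descriptor's distribution across classes."""
    if descriptor not in t.columns:
        raise KeyError(descriptor)
    groups = {
        str(cls): sub[descriptor].to_numpy(dtype=float)
        for cls, sub in t.groupby(by_label)
    }
    groups = {k: v for k, v in groups.items() if len(v) >= 2}
    if len(groups) < 2:
        raise NoComparisonError(
            f"{descriptor}: need >= 2 classes with >= 2 rows each"
        )

    all_vals = np.concatenate(list(groups.values()))
    lo, hi = float(all_vals.min()), float(all_vals.max())
    if lo == hi:
        hi = lo + 1.0
    bins = np.linspace(lo, hi, n_bins + 1)
    counts = {k: np.histogram(v, bins=bins)[0] for k, v in groups.items()}

    p_values: dict[tuple[str, str], float] = {}
    names = sorted(groups)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = groups[names[i]], groups[names[j]]
            if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
                warnings.warn(
                    f"{descriptor}: constant in both classes, test degenerate"
                )
                p = 1.0
            else:
                p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
            p_values[(names[i], names[j])] = p

    return GroupReport(
        descriptor=descriptor,
        bins=bins,
        counts=counts,
        means={k: float(v.mean()) for k, v in groups.items()},
        sds={k: float(v.std(ddof=1)) for k, v in groups.items()},
        p_values=p_values,
    )
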