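"""Three-state secondary-structure assignment (H/E/C).

Backbone hydrogen bonds are detected with the Kabsch–Sander electrostatic
approximation: partial charges of +-0.42 e on C/O and +-0.20 e on N/H give

    E = 0.42 * 0.20 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)  [kcal/mol]

and a bond exists when E < -0.5 kcal/mol. Amide hydrogens are placed 1 Å
from N along the previous residue's C=O direction; missing carbonyl O
atoms are rebuilt from N/CA/C geometry.

Helices (H) follow the canonical alpha pattern (i -> i+4 turns, two in a
row); strands (E) follow parallel/antiparallel bridge ladders; everything
else is coil (C). 3-10 and pi helices are not distinguished: only the
alpha pattern maps to H, which is the simplest defensible 3-state collapse
when only alpha-helix and beta-sheet ratios are consumed downstream.
Minimum segment lengths: H >= 4, E >= 2.
"""

from __future__ import annotations

import numpy as np

from .structure_io import Structure

__all__ = ["HBOND_CUTOFF", "assign_ss", "ss_composition", "kabsch_sander_energy",
           "UndefinedCompositionError"]

HBOND_CUTOFF = -0.5  # kcal/mol
_Q1Q2F = 0.42 * 0.20 * 332.0  # Kabsch-Sander charge product * electrostatic factor


class UndefinedCompositionError(ValueError):
    """Composition requested over an empty residue selection."""


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector in backbone geometry")
    return v / n


def _backbone_frames(s: Structure):
    """Flatten residues to global order with N/CA/C/O/H coordinates.

    Returns (chain_id per residue, within-chain index, N, CA, C, O, H,
    is_proline). H is NaN for chain-initial residues (no preceding C=O)
    and prolines (no amide H).
    """
    chain_ids: list[str] = []
    idxs: list[int] = []
    N, CA, C, O, H = [], [], [], [], []
    is_pro: list[bool] = []
    for cid, residues in s.chains.items():
        for r in residues:
            n = r.atom("N").coords
            ca = r.atom("CA").coords
            c = r.atom("C").coords
            o_atom = r.atom("O")
            if o_atom is not None:
                o = o_atom.coords
            else:
                # rebuild O in the peptide plane: opposite the CA/N(next) bisector
                nxt = residues[r.index + 1] if r.index + 1 < len(residues) else None
                if nxt is not None:
                    d = -_unit(_unit(nxt.atom("N").coords - c) + _unit(ca - c))
                else:
                    d = -_unit(_unit(ca - c) + _unit(n - c))
                o = c + 1.23 * d
            chain_ids.append(cid)
            idxs.append(r.index)
            N.append(n); CA.append(ca); C.append(c); O.append(o)
            is_pro.append(r.three_letter == "PRO")
    N, CA, C, O = map(np.array, (N, CA, C, O))
    H = np.full_like(N, np.nan)
    for k in range(len(N)):
        if is_pro[k] or idxs[k] == 0:
            continue
        prev = k - 1  # same chain because idxs[k] > 0
        H[k] = N[k] + _unit(C[prev] - O[prev])  # 1 Å N-H bond
    return chain_ids, idxs, N, CA, C, O, H, np.array(is_pro)


def kabsch_sander_energy(
    n_d: np.ndarray, h_d: np.ndarray, c_a: np.ndarray, o_a: np.ndarray
) -> float:
    """H-bond energy (kcal/mol) of donor N-H against acceptor C=O."""
    r_on = np.linalg.norm(o_a - n_d)
    r_ch = np.linalg.norm(c_a - h_d)
    r_oh = np.linalg.norm(o_a - h_d)
    r_cn = np.linalg.norm(c_a - n_d)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:  # clashing atoms: treat as bonded
        return -9.9
    return _Q1Q2F * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def _hbond_matrix(s: Structure) -> tuple[np.ndarray, list[str], list[int]]:
    """hb[d, a] True when N-H of residue d donates to C=O of residue a."""
    chain_ids, idxs, N, CA, C, O, H, is_pro = _backbone_frames(s)
    n = len(N)
    hb = np.zeros((n, n), dtype=bool)
    for d in range(n):
        if np.isnan(H[d, 0]):
            continue
        for a in range(n):
            if d == a:
                continue
            if chain_ids[d] == chain_ids[a] and abs(idxs[d] - idxs[a]) < 2:
                continue  # peptide-bonded neighbours are not hydrogen bonds
            if np.linalg.norm(CA[d] - CA[a]) > 9.0:  # KS distance screen
                continue
            if kabsch_sander_energy(N[d], H[d], C[a], O[a]) < HBOND_CUTOFF:
                hb[d, a] = True
    return hb, chain_ids, idxs


def assign_ss(s: Structure) -> dict[tuple[str, int], str]:
    """Per-residue H/E/C labels keyed by ``(chain, index)``.

    Chains shorter than 3 residues are all coil. Helix takes priority over
    strand where patterns overlap.
    """
    labels: dict[tuple[str, int], str] = {
        (cid, r.index): "C" for cid, r in s.iter_residues()
    }
    if all(len(res) < 3 for res in s.chains.values()):
        return labels

    hb, chain_ids, idxs = _hbond_matrix(s)
    n = len(chain_ids)
    key = [(chain_ids[k], idxs[k]) for k in range(n)]
    # same-chain global position lookup for i+k arithmetic
    pos = {key[k]: k for k in range(n)}

    def hbond(acc: int, don: int) -> bool:
        return hb[don, acc]

    def shift(k: int, delta: int) -> int | None:
        target = (chain_ids[k], idxs[k] + delta)
        return pos.get(target)

    # alpha helix: 4-turn at i means CO(i) accepts from NH(i+4);
    # two consecutive turns make residues i+1..i+4 helical
    turn4 = np.zeros(n, dtype=bool)
    for i in range(n):
        j = shift(i, 4)
        if j is not None and hbond(i, j):
            turn4[i] = True
    helix = np.zeros(n, dtype=bool)
    for i in range(n):
        i1 = shift(i, 1)
        if i1 is not None and turn4[i] and turn4[i1]:
            for delta in (1, 2, 3, 4):
                k = shift(i, delta)
                if k is not None:
                    helix[k] = True

    # beta bridges (Kabsch-Sander parallel/antiparallel patterns)
    bridge = np.zeros(n, dtype=bool)
    for i in range(n):
        for j in range(n):
            if chain_ids[i] == chain_ids[j] and abs(idxs[i] - idxs[j]) < 3:
                continue
            im1, ip1 = shift(i, -1), shift(i, 1)
            jm1, jp1 = shift(j, -1), shift(j, 1)
            para = (
                im1 is not None and ip1 is not None
                and hbond(im1, j) and hbond(j, ip1)
            ) or (
                jm1 is not None and jp1 is not None
                and hbond(jm1, i) and hbond(i, jp1)
            )
            anti = hbond(i, j) and hbond(j, i)
            anti = anti or (
                im1 is not None and jp1 is not None
                and jm1 is not None and ip1 is not None
                and hbond(im1, jp1) and hbond(jm1, ip1)
            )
            if para or anti:
                bridge[i] = bridge[j] = True

    strand = bridge & ~helix
    # enforce minimum E segment length of 2 (drop isolated bridges)
    for k in range(n):
        if strand[k]:
            prev_k, next_k = shift(k, -1), shift(k, 1)
            alone = not (
                (prev_k is not None and strand[prev_k])
                or (next_k is not None and strand[next_k])
            )
            if alone:
                strand[k] = False

    for k in range(n):
        if helix[k]:
            labels[key[k]] = "H"
        elif strand[k]:
            labels[key[k]] = "E"
    return labels


def ss_composition(
    labels: dict[tuple[str, int], str] | list[str],
    mask: np.ndarray | list[bool] | None = None,
) -> dict[str, float]:
    """Percent H/E/C over all residues, or over ``mask``-selected residues.

    Percentages sum to 100. An empty selection raises
    :class:`UndefinedCompositionError`.
    """
    seq = list(labels.values()) if isinstance(labels, dict) else list(labels)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if len(mask) != len(seq):
            raise ValueError("mask length must match number of residues")
        seq = [l for l, m in zip(seq, mask) if m]
    if not seq:
        raise UndefinedCompositionError("no residues selected for composition")
    n = len(seq)
    return {
        state: 100.0 * sum(1 for l in seq if l == state) / n
        for state in ("H", "E", "C")
    }
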