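"""Evaluation statistics for inferred haplotypes.

Two scores are implemented.  The *correct phasing ratio* (CPR) compares
inferred haplotypes with known truth at the true SNV positions, under the
optimal one-to-one matching chi between inferred and true haplotypes:

    CPR = sum_k sum_{j in D_chi(k)} 1(H_hat_k(j) = H_true_chi(k)(j))
          / sum_k |D_chi(k)|

where D_m is the set of true SNV positions of true haplotype m.  The
*minimum error correction ratio* (MECR) needs no truth: each read is
charged its per-base disagreement with the best-fitting inferred haplotype
over its interest set O_i, and the total is normalized by the number of
compared bases:

    MECR = sum_i min_k sum_{j in O_i} 1(R_i(j) != H_hat_k(j)) / sum_i |O_i|

Both scores live in [0, 1]; higher CPR and lower MECR are better, and the
two are negatively correlated across datasets, which makes MECR a usable
proxy when truth is unavailable.  SNV calling falls out of the inferred
haplotypes as a byproduct: any position where some haplotype carries a
substitution relative to the reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .model import (
    AlignedRead,
    ConsensusHaplotype,
    ReferenceSequence,
)

__all__ = [
    "EvaluationResult",
    "VariantRecord",
    "true_snv_positions",
    "best_matching",
    "cpr",
    "mecr",
    "call_snvs",
]


class EvaluationError(ValueError):
    pass


@dataclass
class VariantRecord:
    """One called variant: reference position, REF/ALT alleles and the
    per-haplotype allele states (is_snv False flags consensus indels)."""

    position: int
    ref: str
    alts: tuple[str, ...]
    alleles: tuple[str, ...]  # per haplotype, in haplotype order
    is_snv: bool = True


@dataclass
class EvaluationResult:
    cpr: float | None
    mecr: float
    matching: dict[int, int]  # inferred haplotype index -> true index (1-based)
    per_read_best: pd.DataFrame  # read, best haplotype, mismatches, n sites


def true_snv_positions(
    haplotype: ConsensusHaplotype, reference: ReferenceSequence
) -> list[int]:
    """1-based positions where the haplotype substitutes a reference base."""
    hvec = haplotype.codes()
    rvec = reference.codes()
    if hvec.size != rvec.size:
        raise EvaluationError("haplotype length != reference length")
    sub = (hvec != rvec) & (hvec < 4) & (rvec < 4)
    return (np.flatnonzero(sub) + 1).tolist()


def _agreement_matrix(
    true_haps: Sequence[ConsensusHaplotype],
    inferred_haps: Sequence[ConsensusHaplotype],
    snv_sets: Sequence[Iterable[int]],
) -> np.ndarray:
    K = len(true_haps)
    agree = np.zeros((K, K), dtype=float)
    for b, (true_hap, sites) in enumerate(zip(true_haps, snv_sets)):
        pos = np.asarray(sorted(sites), dtype=int)
        if pos.size == 0:
            continue
        t = true_hap.codes()[pos - 1]
        for a, inf_hap in enumerate(inferred_haps):
            agree[a, b] = np.count_nonzero(inf_hap.codes()[pos - 1] == t)
    return agree


def best_matching(
    true_haps: Sequence[ConsensusHaplotype],
    inferred_haps: Sequence[ConsensusHaplotype],
    snv_sets: Sequence[Iterable[int]],
) -> dict[int, int]:
    """Optimal one-to-one matching chi: inferred index -> true index (1-based).

    Maximizes total agreement over the per-true-haplotype SNV sets via the
    assignment problem (equivalent to exhausting all K! permutations).
    """
    if len(true_haps) != len(inferred_haps):
        raise EvaluationError("true and inferred haplotype counts differ")
    if len(snv_sets) != len(true_haps):
        raise EvaluationError("need one SNV set per true haplotype")
    agree = _agreement_matrix(true_haps, inferred_haps, snv_sets)
    rows, cols = linear_sum_assignment(-agree)
    return {int(r) + 1: int(c) + 1 for r, c in zip(rows, cols)}


def cpr(
    true_haps: Sequence[ConsensusHaplotype],
    inferred_haps: Sequence[ConsensusHaplotype],
    true_snv_sets: Sequence[Iterable[int]] | None = None,
    reference: ReferenceSequence | None = None,
) -> float | None:
    """Correct phasing ratio under the optimal haplotype matching.

    ``true_snv_sets`` defaults to each true haplotype's substitution
    positions relative to ``reference``.  Returns None when the union of
    SNV sets is empty (the score is undefined).
    """
    if true_snv_sets is None:
        if reference is None:
            raise EvaluationError("need true_snv_sets or a reference")
        true_snv_sets = [true_snv_positions(h, reference) for h in true_haps]
    sets = [sorted(set(s)) for s in true_snv_sets]
    denom = sum(len(s) for s in sets)
    if denom == 0:
        return None
    agree = _agreement_matrix(true_haps, inferred_haps, sets)
    rows, cols = linear_sum_assignment(-agree)
    return float(agree[rows, cols].sum() / denom)


def mecr(
    reads: Sequence[AlignedRead],
    inferred_haps: Sequence[ConsensusHaplotype],
    sites: Iterable[int] | None = None,
) -> EvaluationResult:
    """Minimum error correction ratio of reads against inferred haplotypes.

    The interest set O_i of read i defaults to all reference positions the
    read covers; ``sites`` restricts it to a given site list (intersection).
    A read/haplotype state pair disagrees when the characters differ; a
    '-' against a base counts one inconsistency, N positions are dropped.
    """
    hvecs = [h.codes() for h in inferred_haps]
    site_arr = None if sites is None else np.asarray(sorted(set(sites)), int)
    num = 0
    den = 0
    rows = []
    for read in reads:
        pos = np.arange(read.start, read.end + 1)
        rvec = read.codes()
        if site_arr is not None:
            mask = np.isin(pos, site_arr)
            pos, rvec = pos[mask], rvec[mask]
        keep = rvec != 5  # drop read N positions
        pos, rvec = pos[keep], rvec[keep]
        if pos.size == 0:
            rows.append((read.name, 0, 0, 0))
            continue
        best_k, best_mm = 0, None
        for k, hvec in enumerate(hvecs):
            h = hvec[pos - 1]
            ok = h != 5
            mm = int(np.count_nonzero(rvec[ok] != h[ok]))
            if best_mm is None or mm < best_mm:
                best_k, best_mm = k, mm
        num += best_mm
        den += int(pos.size)
        rows.append((read.name, best_k + 1, best_mm, int(pos.size)))
    per_read = pd.DataFrame(rows, columns=["read", "haplotype", "mismatches",
                                           "n_sites"])
    score = float(num / den) if den else 0.0
    return EvaluationResult(cpr=None, mecr=score, matching={},
                            per_read_best=per_read)


def call_snvs(
    inferred_haps: Sequence[ConsensusHaplotype],
    reference: ReferenceSequence,
    include_indels: bool = False,
) -> list[VariantRecord]:
    """Emit one record per position where >= 1 haplotype substitutes the
    reference base; consensus deletions are reported only with
    ``include_indels=True`` and flagged ``is_snv=False``.
    """
    rvec = reference.codes()
    hvecs = [h.codes() for h in inferred_haps]
    records: list[VariantRecord] = []
    stacked = np.stack(hvecs)
    sub_any = np.any((stacked != rvec) & (stacked < 4) & (rvec < 4), axis=0)
    del_any = np.any((stacked == 4) & (rvec < 4), axis=0)
    for pos0 in np.flatnonzero(sub_any | (del_any if include_indels else False)):
        ref_base = reference.bases[pos0]
        alleles = tuple("ACGT-N"[v[pos0]] for v in hvecs)
        alts = tuple(sorted({a for a in alleles
                             if a not in (ref_base, "N", "-")}))
        is_snv = bool(sub_any[pos0])
        if not is_snv and not include_indels:
            continue
        records.append(VariantRecord(position=int(pos0) + 1, ref=ref_base,
                                     alts=alts, alleles=alleles, is_snv=is_snv))
    return records
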