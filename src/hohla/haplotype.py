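"""Multi-locus EM haplotype frequency estimation and DR-DQ association.

HLA-DRB1 motifs travel on extended haplotypes with HLA-DQA1 and HLA-DQB1.
Phase across the three loci is unobserved in unrelated subjects, so
haplotype frequencies are estimated by the classic EM algorithm over phase
configurations under Hardy-Weinberg equilibrium, yielding per-subject
posterior haplotype dosages.  Association then contrasts case and control
haplotype frequencies (virtual-reference OR) with a score test on the
pooled-null posterior dosages.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .assoc import (
    AssocResult,
    RARE_COPY_THRESHOLD,
    SubjectCC,
    score_test_arrays,
)
from .catalog import AlleleCatalog, ResiduePosition, motif_of

logger = logging.getLogger(__name__)

__all__ = [
    "MultiLocusGenotype",
    "HaplotypeEstimate",
    "em_haplotype_freqs",
    "dq_haplotype_assoc",
]

#: haplotypes with less estimated mass than this are pruned after convergence
PRUNE_MASS = 1e-6

HAPLOTYPE_SEP = "|"


@dataclass(frozen=True)
class MultiLocusGenotype:
    """Unordered allele pairs at each locus, in a fixed locus order."""

    loci: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        for pair in self.loci:
            if len(pair) != 2:
                raise ValueError("each locus needs exactly two alleles")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def n_het(self) -> int:
        return sum(1 for a, b in self.loci if a != b)

    def phase_pairs(self) -> list[tuple[tuple[str, ...], tuple[str, ...]]]:
        """All ordered resolutions of phase: 2^h for h heterozygous loci."""
        pairs: list[tuple[tuple[str, ...], tuple[str, ...]]] = [((), ())]
        for a, b in self.loci:
            nxt = []
            for h1, h2 in pairs:
                nxt.append((h1 + (a,), h2 + (b,)))
                if a != b:
                    nxt.append((h1 + (b,), h2 + (a,)))
            pairs = nxt
        return pairs


def _hap_label(hap: tuple[str, ...]) -> str:
    return HAPLOTYPE_SEP.join(hap)


@dataclass
class HaplotypeEstimate:
    """EM output: frequencies, per-subject posterior dosages, loglik trace."""

    haplotypes: list[str]
    frequencies: np.ndarray
    posterior_dosage: np.ndarray  # subjects x haplotypes, rows sum to 2
    loglik_trace: list[float]
    converged: bool
    n_iter: int

    def freq(self, haplotype: str) -> float:
        try:
            return float(self.frequencies[self.haplotypes.index(haplotype)])
        except ValueError:
            return 0.0

    def dosage(self, haplotype: str) -> np.ndarray:
        try:
            return self.posterior_dosage[:, self.haplotypes.index(haplotype)]
        except ValueError:
            return np.zeros(self.posterior_dosage.shape[0])

    def expected_count(self, haplotype: str) -> float:
        return float(self.dosage(haplotype).sum())


def em_haplotype_freqs(
    genotypes: Sequence[MultiLocusGenotype],
    tol: float = 1e-10,
    max_iter: int = 1000,
    seed: int = 0,
) -> HaplotypeEstimate:
    """EM estimate of haplotype frequencies under Hardy-Weinberg phase mixing.

    Starts from the uniform distribution over all haplotypes compatible with
    at least one subject (a deterministic start; ``seed`` is accepted for
    interface symmetry but the algorithm is deterministic), iterates
    expectation over phase configurations and maximization of frequencies,
    and stops when the log-likelihood gain drops below ``tol``.  Haplotypes
    with final mass below ``1e-6`` are pruned.  The log-likelihood is
    nondecreasing by construction; hitting ``max_iter`` flags the result as
    unconverged rather than raising.
    """
    if not genotypes:
        raise ValueError("need at least one genotype")
    n_loci = genotypes[0].n_loci
    if any(g.n_loci != n_loci for g in genotypes):
        raise ValueError("loci not aligned across subjects")

    # enumerate each subject's compatible ordered phase pairs once
    hap_index: dict[tuple[str, ...], int] = {}
    subj_pairs: list[tuple[np.ndarray, np.ndarray]] = []
    for g in genotypes:
        p1, p2 = [], []
        for h1, h2 in g.phase_pairs():
            for h in (h1, h2):
                if h not in hap_index:
                    hap_index[h] = len(hap_index)
            p1.append(hap_index[h1])
            p2.append(hap_index[h2])
        subj_pairs.append((np.array(p1), np.array(p2)))

    H = len(hap_index)
    haps = [None] * H
    for h, i in hap_index.items():
        haps[i] = h
    f = np.full(H, 1.0 / H)

    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        counts = np.zeros(H)
        loglik = 0.0
        for p1, p2 in subj_pairs:
            w = f[p1] * f[p2]
            tot = w.sum()
            loglik += math.log(tot)
            w /= tot
            np.add.at(counts, p1, w)
            np.add.at(counts, p2, w)
        f_new = counts / (2 * len(genotypes))
        trace.append(loglik)
        if len(trace) > 1 and trace[-1] - trace[-2] < tol:
            converged = True
            f = f_new
            break
        f = f_new
    if not converged:
        logger.warning("EM reached max_iter=%d without converging", max_iter)

    # final posterior dosages at the converged frequencies
    dosage = np.zeros((len(genotypes), H))
    for i, (p1, p2) in enumerate(subj_pairs):
        w = f[p1] * f[p2]
        w /= w.sum()
        np.add.at(dosage[i], p1, w)
        np.add.at(dosage[i], p2, w)

    keep = np.flatnonzero((f >= PRUNE_MASS) | (dosage.sum(axis=0) >= PRUNE_MASS))
    f = f[keep]
    f = f / f.sum()
    dosage = dosage[:, keep]
    labels = [_hap_label(haps[i]) for i in keep]
    order = np.argsort(labels)
    return HaplotypeEstimate(
        haplotypes=[labels[i] for i in order],
        frequencies=f[order],
        posterior_dosage=dosage[:, order],
        loglik_trace=trace,
        converged=converged,
        n_iter=it,
    )


def _counting_estimate(genotypes: Sequence[MultiLocusGenotype]) -> HaplotypeEstimate:
    """Direct tally over phase-unambiguous subjects (the config alternative)."""
    labels: dict[str, int] = {}
    rows = []
    for g in genotypes:
        row: dict[str, float] = {}
        if g.n_het() <= 1:
            (h1, h2) = g.phase_pairs()[0]
            for h in (h1, h2):
                lab = _hap_label(h)
                labels.setdefault(lab, 0)
                row[lab] = row.get(lab, 0) + 1.0
        rows.append(row)
    if not labels:
        raise ValueError("no phase-unambiguous subjects to count")
    haps = sorted(labels)
    dosage = np.zeros((len(genotypes), len(haps)))
    for i, row in enumerate(rows):
        for lab, c in row.items():
            dosage[i, haps.index(lab)] = c
    counts = dosage.sum(axis=0)
    return HaplotypeEstimate(
        haplotypes=haps,
        frequencies=counts / counts.sum(),
        posterior_dosage=dosage,
        loglik_trace=[],
        converged=True,
        n_iter=0,
    )


def subject_genotype(
    subject: SubjectCC,
    catalog: AlleleCatalog,
    motif_positions: Sequence[ResiduePosition],
) -> MultiLocusGenotype:
    """(DRB1-motif, DQA1, DQB1) genotype for one subject.

    The DRB1 locus is recoded to the allele's motif at the screened
    positions, so haplotypes read ``motif|DQA1|DQB1``.
    """
    if subject.dqa1 is None or subject.dqb1 is None:
        raise ValueError(f"subject {subject.id}: DQA1/DQB1 genotype required")
    motifs = tuple(
        motif_of(catalog, a, motif_positions).residues for a in subject.drb1
    )
    return MultiLocusGenotype(
        loci=(
            motifs,
            tuple(a.canonical for a in subject.dqa1),
            tuple(a.canonical for a in subject.dqb1),
        )
    )


def dq_haplotype_assoc(
    subjects: Sequence[SubjectCC],
    catalog: AlleleCatalog,
    motif_positions: Sequence[ResiduePosition],
    covariates: Sequence[str] = (),
    use_em: bool = True,
) -> list[AssocResult]:
    """DRB1-motif x DQA1 x DQB1 haplotype association table.

    Frequencies come from group-specific EM runs (cases and controls
    separately), mirroring per-group frequency columns; the score test uses
    posterior dosages from a pooled EM fit so the null model is shared.
    Haplotypes observed in only one group are reported with counts and
    flagged; a haplotype absent among cases has OR = 0 and no Z.  With
    ``use_em=False`` frequencies come from direct counting over
    phase-unambiguous subjects instead.
    """
    cases = [s for s in subjects if s.y == 1]
    ctrls = [s for s in subjects if s.y == 0]
    if not cases or not ctrls:
        raise ValueError("need both cases and controls")
    geno = {id(s): subject_genotype(s, catalog, motif_positions) for s in subjects}
    estimator = em_haplotype_freqs if use_em else _counting_estimate
    est_case = estimator([geno[id(s)] for s in cases])
    est_ctrl = estimator([geno[id(s)] for s in ctrls])
    est_pool = estimator([geno[id(s)] for s in subjects])

    y = np.array([s.y for s in subjects], dtype=float)
    X = (
        np.array([[s.covariates[c] for c in covariates] for s in subjects])
        if covariates
        else None
    )

    results = []
    for hap in sorted(set(est_case.haplotypes) | set(est_ctrl.haplotypes)):
        fc, ft = est_case.freq(hap), est_ctrl.freq(hap)
        nc = int(round(est_case.expected_count(hap)))
        nt = int(round(est_ctrl.expected_count(hap)))
        flags: list[str] = []
        if nc + nt < RARE_COPY_THRESHOLD:
            flags.append("rare")
        OR = Z = SE = p = math.nan
        if fc == 0:
            OR = 0.0
            flags.append("case_only_absent")
        elif ft == 0:
            flags.append("control_only_absent" if nc else "or_undefined")
            flags.append("or_undefined")
        else:
            OR = fc / ft
        if fc > 0 and ft > 0:
            d = est_pool.dosage(hap)
            if np.ptp(d) > 0:
                Z, p = score_test_arrays(y, d, X)
                if Z != 0 and OR > 0:
                    SE = math.log(OR) / Z
        results.append(
            AssocResult(
                category=hap, n_case=nc, n_ctrl=nt, f_case=fc, f_ctrl=ft,
                OR=OR, Z=Z, SE=SE, p=p, flags=tuple(dict.fromkeys(flags)),
            )
        )
    return results
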