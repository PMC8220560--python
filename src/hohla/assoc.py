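"""Case-control association of alleles, residues and motifs (HOH step 2).

Within a cluster of similar alleles the analysis proceeds in three layers:

* **Residue screening** removes positions that cannot carry the cluster's
  disease signal: monomorphic positions, positions whose only variation sits
  on rare alleles (< 3 chromosome copies), and the later member of any pair
  of positions whose amino-acid assignments are a bijection (complete LD)
  across the common alleles.
* **Virtual-reference odds ratios**: for a category (allele, amino acid, or
  motif) the OR is the case chromosome frequency divided by the control
  chromosome frequency of that same category — no reference category is
  chosen, so the OR is invariant to how the remaining categories are
  labelled.
* **Score test**: significance comes from the score statistic of the
  category's chromosome dosage (0..2 per subject) in a logistic model of
  case status, evaluated under the null fit (intercept only, or intercept
  plus covariates).  Z is signed so that enrichment in cases is positive;
  the standard error, when needed, is the derived SE = log(OR)/Z.

Frequencies are chromosome-based: each subject contributes two chromosomes
to their group.  p-values are two-sided normal and reported unadjusted for
multiple comparisons.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import (
    MISSING,
    AlleleCatalog,
    AlleleName,
    Motif,
    ResiduePosition,
    motif_of,
    parse_allele_name,
)
from .hierarchy import Cluster

logger = logging.getLogger(__name__)

__all__ = [
    "SubjectCC",
    "CategoryCounts",
    "AssocResult",
    "ResidueScreenReport",
    "RARE_COPY_THRESHOLD",
    "ANTIBODY_COLUMNS",
    "chromosome_counts",
    "screen_residues",
    "virtual_reference_or",
    "score_test",
    "score_test_arrays",
    "fisher_compare",
    "motif_assoc_table",
    "residue_assoc_table",
    "allele_assoc_table",
    "antibody_assoc",
    "read_subjects_cc",
    "write_subjects_cc",
    "write_assoc_tsv",
]

#: categories or alleles seen on fewer chromosomes than this are "rare"
RARE_COPY_THRESHOLD = 3

ANTIBODY_COLUMNS = ("GADA", "IA2A", "IAA", "ZnT8RA", "ZnT8WA", "ZnT8QA")

Mapper = Callable[[AlleleName], Optional[str]]


@dataclass
class SubjectCC:
    """One case-control subject: disease status plus genotypes."""

    id: str
    y: int
    drb1: tuple[AlleleName, AlleleName]
    dqa1: Optional[tuple[AlleleName, AlleleName]] = None
    dqb1: Optional[tuple[AlleleName, AlleleName]] = None
    antibodies: dict[str, int] = field(default_factory=dict)
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.y not in (0, 1):
            raise ValueError(f"subject {self.id}: y must be 0 or 1")


@dataclass
class CategoryCounts:
    """Chromosome counts and within-group frequencies per category."""

    categories: list[str]
    n_case: dict[str, int]
    n_ctrl: dict[str, int]

    @property
    def total_case(self) -> int:
        return sum(self.n_case.values())

    @property
    def total_ctrl(self) -> int:
        return sum(self.n_ctrl.values())

    def f_case(self, category: str) -> float:
        return self.n_case.get(category, 0) / self.total_case

    def f_ctrl(self, category: str) -> float:
        return self.n_ctrl.get(category, 0) / self.total_ctrl

    def total(self, category: str) -> int:
        return self.n_case.get(category, 0) + self.n_ctrl.get(category, 0)


@dataclass
class AssocResult:
    """Association summary for one category (one row of an output table)."""

    category: str
    n_case: int
    n_ctrl: int
    f_case: float
    f_ctrl: float
    OR: float = math.nan
    Z: float = math.nan
    SE: float = math.nan
    p: float = math.nan
    flags: tuple[str, ...] = ()


@dataclass
class ResidueScreenReport:
    """Disposition of every screened position within a cluster."""

    status: dict[ResiduePosition, str]  # kept | monomorphic | near_monomorphic | rare | collapsed_LD
    ld_partner: dict[ResiduePosition, ResiduePosition]
    rare_alleles: list[AlleleName]
    warnings: list[str]

    def kept(self) -> list[ResiduePosition]:
        return [p for p, s in self.status.items() if s == "kept"]


# ---------------------------------------------------------------------------
# counting


def chromosome_counts(
    subjects: Sequence[SubjectCC],
    mapper: Mapper,
    drop_unmapped: bool = False,
) -> CategoryCounts:
    """Tally chromosomes per category in cases and controls.

    Each subject contributes two chromosomes to their group.  A chromosome
    whose allele maps to ``None`` becomes category ``"OTHER"`` unless
    ``drop_unmapped`` is set (used for within-cluster analyses, where
    non-cluster chromosomes are excluded rather than lumped).
    """
    n_case: dict[str, int] = {}
    n_ctrl: dict[str, int] = {}
    for s in subjects:
        tgt = n_case if s.y == 1 else n_ctrl
        for allele in s.drb1:
            cat = mapper(allele)
            if cat is None:
                if drop_unmapped:
                    continue
                cat = "OTHER"
            tgt[cat] = tgt.get(cat, 0) + 1
    if not n_case or not n_ctrl:
        raise ValueError("need at least one counted chromosome in each group")
    cats = sorted(set(n_case) | set(n_ctrl))
    return CategoryCounts(categories=cats, n_case=n_case, n_ctrl=n_ctrl)


def category_dosage(subject: SubjectCC, mapper: Mapper, category: str) -> int:
    """Number of the subject's chromosomes (0..2) mapping to ``category``."""
    return sum(1 for a in subject.drb1 if (mapper(a) or "OTHER") == category)


# ---------------------------------------------------------------------------
# residue screening


def screen_residues(
    catalog: AlleleCatalog,
    cluster: Cluster,
    subjects: Sequence[SubjectCC],
    positions: Sequence[ResiduePosition],
) -> ResidueScreenReport:
    """Classify each position within the cluster for downstream analysis.

    An allele is *rare* when observed on fewer than ``RARE_COPY_THRESHOLD``
    chromosomes over the whole sample (cases plus controls).  A position is
    ``monomorphic`` if a single amino acid occurs on every cluster allele,
    ``near_monomorphic`` if its only variation sits on rare alleles, and
    ``collapsed_LD`` if an earlier kept position determines it through a
    bijection of amino-acid assignments across the non-rare alleles (the
    later position is dropped; its partner is recorded).  Alleles with a
    missing residue at a position are excluded from that position with a
    logged warning.
    """
    copies: dict[AlleleName, int] = {a: 0 for a in cluster.members}
    for s in subjects:
        for allele in s.drb1:
            if allele in copies:
                copies[allele] += 1
    rare = [a for a, c in copies.items() if c < RARE_COPY_THRESHOLD]
    common = [a for a in sorted(cluster.members) if a not in rare]

    status: dict[ResiduePosition, str] = {}
    ld_partner: dict[ResiduePosition, ResiduePosition] = {}
    warn: list[str] = []

    def assignments(pos: ResiduePosition, alleles: Iterable[AlleleName]) -> dict[AlleleName, str]:
        out = {}
        for a in alleles:
            aa = catalog.residue(a, pos)
            if aa == MISSING:
                msg = f"{a.canonical} missing residue at {pos.label}; excluded there"
                warn.append(msg)
                logger.warning(msg)
                continue
            out[a] = aa
        return out

    kept_so_far: list[ResiduePosition] = []
    for pos in positions:
        all_aa = assignments(pos, sorted(cluster.members))
        common_aa = {a: aa for a, aa in all_aa.items() if a in common}
        if len(set(all_aa.values())) <= 1:
            status[pos] = "monomorphic"
            continue
        if len(set(common_aa.values())) <= 1:
            status[pos] = "near_monomorphic"
            continue
        # minor amino acids carried only by rare alleles, with < threshold
        # copies in total, cannot support an association
        aa_copies: dict[str, int] = {}
        for a, aa in all_aa.items():
            aa_copies[aa] = aa_copies.get(aa, 0) + copies.get(a, 0)
        modal = max(aa_copies, key=aa_copies.get)
        if all(c < RARE_COPY_THRESHOLD for aa, c in aa_copies.items() if aa != modal):
            status[pos] = "rare"
            continue
        # complete LD with an earlier kept position: bijective assignment
        collapsed = False
        for prev in kept_so_far:
            prev_aa = {a: aa for a, aa in assignments(prev, common).items()}
            shared = [a for a in common_aa if a in prev_aa]
            fwd: dict[str, str] = {}
            rev: dict[str, str] = {}
            bijective = True
            for a in shared:
                x, yv = prev_aa[a], common_aa[a]
                if fwd.setdefault(x, yv) != yv or rev.setdefault(yv, x) != x:
                    bijective = False
                    break
            if bijective and len(set(fwd.values())) == len(fwd) and len(fwd) > 1:
                status[pos] = "collapsed_LD"
                ld_partner[pos] = prev
                collapsed = True
                break
        if not collapsed:
            status[pos] = "kept"
            kept_so_far.append(pos)
    return ResidueScreenReport(
        status=status, ld_partner=ld_partner, rare_alleles=sorted(rare), warnings=warn
    )


# ---------------------------------------------------------------------------
# score test


def score_test_arrays(
    y: np.ndarray, d: np.ndarray, X: Optional[np.ndarray] = None
) -> tuple[float, float]:
    """Score test of dosage ``d`` against binary ``y`` under a null logistic fit.

    With null fitted probabilities ``mu``, the score is
    ``U = sum((y - mu) * d)`` and its null variance is
    ``V = sum(w d^2) - c' I^{-1} c`` with ``w = mu (1 - mu)``, where ``c`` is
    the cross-information between dosage and the null design (intercept plus
    covariates) and ``I`` the null information.  Returns ``(Z, p)`` with
    ``Z = U / sqrt(V)`` and a two-sided normal p-value.

    Raises
    ------
    ValueError
        If both outcome classes are not present, or ``V <= 0`` (degenerate
        design / separation).
    """
    y = np.asarray(y, dtype=float)
    d = np.asarray(d, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("dosage must be finite")
    if y.min() == y.max():
        raise ValueError("need at least one case and one control")
    if np.ptp(d) == 0:
        return 0.0, 1.0  # constant dosage carries no information
    n = len(y)
    ones = np.ones((n, 1))
    if X is None or (hasattr(X, "size") and X.size == 0):
        design = ones
        mu = np.full(n, y.mean())
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        design = np.hstack([ones, X])
        import statsmodels.api as sm

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(y, design, family=sm.families.Binomial()).fit()
        mu = np.asarray(fit.fittedvalues)
    w = mu * (1.0 - mu)
    U = float(np.sum((y - mu) * d))
    c = design.T @ (w * d)
    info = design.T @ (design * w[:, None])
    # pinv keeps the projection well defined under collinear covariates
    V = float(np.sum(w * d * d) - c @ np.linalg.pinv(info) @ c)
    if V <= 0:
        raise ValueError("score variance non-positive (degenerate design)")
    Z = U / math.sqrt(V)
    p = 2.0 * stats.norm.sf(abs(Z))
    return Z, float(p)


def score_test(
    subjects: Sequence[SubjectCC],
    dosage: Callable[[SubjectCC], float],
    covariates: Sequence[str] = (),
    outcome: Callable[[SubjectCC], int] = lambda s: s.y,
) -> tuple[float, float]:
    """Subject-level wrapper around :func:`score_test_arrays`.

    ``dosage`` maps a subject to their expected category dosage in [0, 2];
    ``covariates`` names entries of each subject's covariate map that enter
    the null model (intercept only when empty).
    """
    y = np.array([outcome(s) for s in subjects], dtype=float)
    d = np.array([dosage(s) for s in subjects], dtype=float)
    X = (
        np.array([[s.covariates[c] for c in covariates] for s in subjects], dtype=float)
        if covariates
        else None
    )
    return score_test_arrays(y, d, X)


# ---------------------------------------------------------------------------
# virtual-reference OR and friends


def virtual_reference_or(
    counts: CategoryCounts,
    category: str,
    subjects: Optional[Sequence[SubjectCC]] = None,
    mapper: Optional[Mapper] = None,
    covariates: Sequence[str] = (),
    outcome: Callable[[SubjectCC], int] = lambda s: s.y,
) -> AssocResult:
    """Virtual-reference odds ratio with score-test significance.

    OR is the case/control frequency ratio of the category itself.  When
    ``subjects`` and ``mapper`` are supplied, Z and p come from the score
    test of the category's chromosome dosage and SE is derived as
    ``log(OR)/Z``; with Z = 0 (or OR undefined) the SE is flagged undefined.
    A category absent from controls has no finite OR and is reported with
    counts only, flagged ``or_undefined``.
    """
    nc = counts.n_case.get(category, 0)
    nt = counts.n_ctrl.get(category, 0)
    fc, ft = counts.f_case(category), counts.f_ctrl(category)
    flags: list[str] = []
    if counts.total(category) < RARE_COPY_THRESHOLD:
        flags.append("rare")
    OR = math.nan
    if ft > 0:
        OR = fc / ft
    else:
        flags.append("or_undefined")
    Z = SE = p = math.nan
    if subjects is not None and mapper is not None:
        Z, p = score_test(
            subjects,
            lambda s: category_dosage(s, mapper, category),
            covariates,
            outcome,
        )
        if Z != 0 and math.isfinite(OR) and OR > 0:
            SE = math.log(OR) / Z
        else:
            flags.append("se_undefined")
    return AssocResult(
        category=category, n_case=nc, n_ctrl=nt, f_case=fc, f_ctrl=ft,
        OR=OR, Z=Z, SE=SE, p=p, flags=tuple(flags),
    )


def fisher_compare(counts: CategoryCounts, category_a: str, category_b: str) -> float:
    """Two-sided Fisher exact p comparing two categories' case/control counts."""
    table = np.array(
        [
            [counts.n_case.get(category_a, 0), counts.n_ctrl.get(category_a, 0)],
            [counts.n_case.get(category_b, 0), counts.n_ctrl.get(category_b, 0)],
        ]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        logger.warning(
            "fisher_compare(%s, %s): zero margin, p set to 1", category_a, category_b
        )
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def _assoc_table(
    subjects: Sequence[SubjectCC],
    mapper: Mapper,
    drop_unmapped: bool,
    covariates: Sequence[str],
    outcome: Callable[[SubjectCC], int] = lambda s: s.y,
) -> list[AssocResult]:
    counts = chromosome_counts(subjects, mapper, drop_unmapped=drop_unmapped)
    return [
        virtual_reference_or(counts, cat, subjects, mapper, covariates, outcome)
        for cat in counts.categories
    ]


def allele_assoc_table(
    subjects: Sequence[SubjectCC],
    covariates: Sequence[str] = (),
    resolution_fields: int = 2,
) -> list[AssocResult]:
    """Per-allele association over the whole sample (allele-frequency table)."""
    return _assoc_table(
        subjects, lambda a: a.truncate(resolution_fields).canonical, False, covariates
    )


def _cluster_restricted(
    subjects: Sequence[SubjectCC], cluster: Cluster
) -> list[SubjectCC]:
    return [s for s in subjects if any(a in cluster for a in s.drb1)]


def residue_assoc_table(
    subjects: Sequence[SubjectCC],
    catalog: AlleleCatalog,
    cluster: Cluster,
    position: ResiduePosition,
    covariates: Sequence[str] = (),
) -> list[AssocResult]:
    """Per-amino-acid association at one position among cluster carriers.

    Restricted to subjects carrying at least one cluster allele; only
    cluster chromosomes are counted (non-cluster chromosomes are dropped,
    not lumped into a reference).
    """

    def mapper(a: AlleleName) -> Optional[str]:
        if a not in cluster:
            return None
        aa = catalog.residue(a, position)
        return None if aa == MISSING else aa

    return _assoc_table(_cluster_restricted(subjects, cluster), mapper, True, covariates)


def motif_mapper(
    catalog: AlleleCatalog,
    positions: Sequence[ResiduePosition],
    cluster: Optional[Cluster] = None,
) -> Mapper:
    """Mapper from an allele to its motif string (None outside the cluster)."""

    def mapper(a: AlleleName) -> Optional[str]:
        if cluster is not None and a not in cluster:
            return None
        try:
            return motif_of(catalog, a, positions).residues
        except (KeyError, ValueError):
            return None

    return mapper


def motif_assoc_table(
    subjects: Sequence[SubjectCC],
    catalog: AlleleCatalog,
    positions: Sequence[ResiduePosition],
    cluster: Optional[Cluster] = None,
    covariates: Sequence[str] = (),
) -> list[AssocResult]:
    """Per-motif association at the screened positions.

    With a cluster given, the analysis is restricted to cluster carriers and
    cluster chromosomes.  Motifs seen on fewer than three chromosomes are
    flagged rare.
    """
    mapper = motif_mapper(catalog, positions, cluster)
    subs = _cluster_restricted(subjects, cluster) if cluster is not None else subjects
    return _assoc_table(subs, mapper, cluster is not None, covariates)


def antibody_assoc(
    cases: Sequence[SubjectCC],
    catalog: AlleleCatalog,
    positions: Sequence[ResiduePosition],
    motif: str,
    antibody: str,
    cluster: Optional[Cluster] = None,
    covariates: Sequence[str] = (),
) -> AssocResult:
    """Association of a motif with autoantibody positivity among patients.

    Case status is replaced by the antibody flag: the OR contrasts the motif
    frequency among antibody-positive versus antibody-negative patients.
    Patients lacking the antibody measurement are excluded (count logged).

    Raises
    ------
    ValueError
        If any subject is a control, or the antibody is all-positive or
        all-negative among measured patients.
    """
    if any(s.y != 1 for s in cases):
        raise ValueError("antibody association is defined among patients only")
    measured = [s for s in cases if antibody in s.antibodies]
    dropped = len(cases) - len(measured)
    if dropped:
        logger.info("antibody_assoc(%s): %d patients without measurement excluded",
                    antibody, dropped)
    flags = {s.antibodies[antibody] for s in measured}
    if flags <= {0} or flags <= {1}:
        raise ValueError(f"antibody {antibody} has no variation among patients")
    if cluster is not None:
        measured = [s for s in measured if any(a in cluster for a in s.drb1)]
    mapper = motif_mapper(catalog, positions, cluster)
    outcome = lambda s: s.antibodies[antibody]  # noqa: E731
    counts = chromosome_counts_by(measured, mapper, outcome, cluster is not None)
    return virtual_reference_or(counts, motif, measured, mapper, covariates, outcome)


def chromosome_counts_by(
    subjects: Sequence[SubjectCC],
    mapper: Mapper,
    outcome: Callable[[SubjectCC], int],
    drop_unmapped: bool = False,
) -> CategoryCounts:
    """Like :func:`chromosome_counts` but splitting groups by ``outcome``."""
    n_pos: dict[str, int] = {}
    n_neg: dict[str, int] = {}
    for s in subjects:
        tgt = n_pos if outcome(s) == 1 else n_neg
        for allele in s.drb1:
            cat = mapper(allele)
            if cat is None:
                if drop_unmapped:
                    continue
                cat = "OTHER"
            tgt[cat] = tgt.get(cat, 0) + 1
    if not n_pos or not n_neg:
        raise ValueError("need counted chromosomes in both outcome groups")
    cats = sorted(set(n_pos) | set(n_neg))
    return CategoryCounts(categories=cats, n_case=n_pos, n_ctrl=n_neg)


# ---------------------------------------------------------------------------
# I/O


def _pair(row: Mapping, prefix: str) -> Optional[tuple[AlleleName, AlleleName]]:
    a, b = row.get(f"{prefix}_1"), row.get(f"{prefix}_2")
    if a is None or b is None or pd.isna(a) or pd.isna(b):
        return None
    return (parse_allele_name(str(a)), parse_allele_name(str(b)))


def read_subjects_cc(path: str | Path) -> list[SubjectCC]:
    """Read the case-control subject TSV.

    Required columns: ``id``, ``y``, ``drb1_1``, ``drb1_2``.  Optional:
    ``dqa1_1/2``, ``dqb1_1/2``, the antibody flag columns, and any further
    numeric columns, which become covariates.
    """
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    required = {"id", "y", "drb1_1", "drb1_2"}
    if not required <= set(df.columns):
        raise ValueError(f"subject table must have columns {sorted(required)}")
    known = required | {"dqa1_1", "dqa1_2", "dqb1_1", "dqb1_2"} | set(ANTIBODY_COLUMNS)
    covar_cols = [c for c in df.columns if c not in known]
    subjects = []
    for _, row in df.iterrows():
        drb1 = _pair(row, "drb1")
        if drb1 is None:
            raise ValueError(f"subject {row['id']}: incomplete DRB1 genotype")
        antibodies = {
            ab: int(row[ab]) for ab in ANTIBODY_COLUMNS
            if ab in df.columns and not pd.isna(row[ab])
        }
        subjects.append(
            SubjectCC(
                id=str(row["id"]),
                y=int(row["y"]),
                drb1=drb1,
                dqa1=_pair(row, "dqa1"),
                dqb1=_pair(row, "dqb1"),
                antibodies=antibodies,
                covariates={c: float(row[c]) for c in covar_cols if not pd.isna(row[c])},
            )
        )
    return subjects


def write_subjects_cc(subjects: Sequence[SubjectCC], path: str | Path) -> None:
    rows = []
    for s in subjects:
        row: dict = {
            "id": s.id, "y": s.y,
            "drb1_1": s.drb1[0].canonical, "drb1_2": s.drb1[1].canonical,
        }
        if s.dqa1:
            row["dqa1_1"], row["dqa1_2"] = s.dqa1[0].canonical, s.dqa1[1].canonical
        if s.dqb1:
            row["dqb1_1"], row["dqb1_2"] = s.dqb1[0].canonical, s.dqb1[1].canonical
        row.update(s.antibodies)
        row.update(s.covariates)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def assoc_frame(results: Sequence[AssocResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "category": r.category,
                "n_case": r.n_case, "f_case": r.f_case,
                "n_ctrl": r.n_ctrl, "f_ctrl": r.f_ctrl,
                "OR": r.OR, "Z": r.Z, "SE": r.SE, "p": r.p,
                "flags": ";".join(r.flags),
            }
            for r in results
        ]
    )


def write_assoc_tsv(results: Sequence[AssocResult], path: str | Path) -> None:
    assoc_frame(results).to_csv(path, sep="\t", index=False)
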