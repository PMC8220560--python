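"""Synthetic allele catalogs, case-control samples, and birth-cohort panels.

Every generator plants known structure so each pipeline stage can be tested
against ground truth: a catalog whose cluster geometry and screening-position
residues are fixed by construction, a logistic disease model with per-motif
chromosome effects sampled case-control by rejection, and a Weibull
proportional-hazards seroconversion model observed through noisy antibody
trajectories on a scheduled visit grid.  Each simulator returns its latent
truth (linear predictors, latent event times) in a sidecar frame that the
analysis modules never read.

The packaged DR4 preset is a *synthetic* stand-in for a curated reference
alignment: it pins exactly the cluster structure the analyses exercise (the
β37/β57/β67/β70/β71/β74/β86 dispositions, the seven (β71, β74, β86) motifs
with KAG on DRB1*04:01 only, RAV on 04:04/04:10, REG on 04:07, the rare KAV
on 04:06) plus neutral backbone variation, and nothing more.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .assoc import SubjectCC
from .catalog import (
    AlleleCatalog,
    AlleleName,
    ResiduePosition,
    motif_of,
    parse_allele_name,
    positions_from_indices,
)
from .survival import ANTIBODIES, AntibodyPanel, SubjectCohort

__all__ = [
    "FIXTURE_POSITION_INDICES",
    "DR4_SCREEN_INDICES",
    "MOTIF_INDICES",
    "dr4_fixture_catalog",
    "dr4_fixture_subjects",
    "dr4_cluster_names",
    "make_allele_pool",
    "SimConfigCC",
    "SimCCResult",
    "simulate_case_control",
    "SimConfigCohort",
    "SimCohortResult",
    "simulate_cohort",
    "default_visit_schedule",
]

AA = "ACDEFGHIKLMNPQRSTVWY"

# ---------------------------------------------------------------------------
# the DR4 fixture catalog

#: alignment columns of the fixture (three signal-peptide, 32 mature)
FIXTURE_POSITION_INDICES = (
    -29, -17, -1,
    9, 11, 13, 26, 28, 30, 32, 37, 40, 47, 57, 60, 67, 70, 71, 74, 77,
    85, 86, 90, 96, 98, 104, 112, 120, 133, 140, 152, 160, 180, 200, 233,
)

#: the within-cluster screening positions
DR4_SCREEN_INDICES = (37, 57, 67, 70, 71, 74, 86)

#: the three residues forming the risk motifs
MOTIF_INDICES = (71, 74, 86)

_BACKBONE = {
    -29: "M", -17: "A", -1: "G",
    9: "E", 11: "V", 13: "H", 26: "F", 28: "D", 30: "Y", 32: "Y", 37: "Y",
    40: "S", 47: "Y", 57: "D", 60: "Y", 67: "L", 70: "Q", 71: "R", 74: "A",
    77: "T", 85: "V", 86: "G", 90: "T", 96: "Q", 98: "E", 104: "A",
    112: "H", 120: "N", 133: "L", 140: "T", 152: "V", 160: "D", 180: "L",
    200: "T", 233: "R",
}

#: per-allele deviations from the DR4 backbone
_FIXTURE_OVERRIDES: dict[str, dict[int, str]] = {
    # DR4 cluster — motif residues at (71, 74, 86) plus light backbone drift
    "DRB1*04:01": {71: "K"},                                        # KAG
    "DRB1*04:02": {67: "I", 70: "D", 71: "E", 86: "V"},             # EAV
    "DRB1*04:03": {74: "E", 77: "S", 90: "A", 104: "S", 86: "V"},   # REV
    "DRB1*04:04": {9: "W", 86: "V"},                                # RAV
    "DRB1*04:05": {57: "S", 67: "I", 70: "D"},                      # RAG
    "DRB1*04:06": {37: "S", 71: "K", 86: "V"},                      # KAV (rare)
    "DRB1*04:07": {74: "E", 77: "S", 90: "A", 104: "S"},            # REG
    "DRB1*04:08": {},                                               # RAG
    "DRB1*04:10": {9: "W", 86: "V", 160: "A"},                      # RAV
    "DRB1*04:13": {96: "E"},                                        # RAG
    # outgroup alleles — many backbone substitutions
    "DRB1*01:01": {9: "W", 11: "L", 13: "F", 26: "L", 28: "E", 30: "C",
                   32: "H", 40: "F", 47: "W", 60: "H", 112: "Q"},
    "DRB1*03:01": {9: "K", 11: "S", 13: "S", 26: "Y", 28: "N", 30: "H",
                   47: "F", 60: "S", 71: "K", 74: "R", 77: "N", 86: "V",
                   90: "R"},                                        # KRV
    "DRB1*03:02": {9: "K", 11: "S", 13: "S", 26: "Y", 28: "N", 30: "H",
                   47: "F", 60: "S", 71: "K", 74: "R", 77: "N", 90: "R",
                   98: "K"},                                        # KRG
    "DRB1*07:01": {9: "Q", 11: "G", 13: "Y", 26: "W", 28: "E", 32: "N",
                   40: "A", 60: "L", 67: "F", 70: "R", 74: "Q", 120: "S"},
    "DRB1*08:01": {9: "D", 11: "S", 13: "G", 28: "H", 30: "G", 40: "T",
                   47: "L", 74: "L", 133: "M", 152: "A"},
    "DRB1*15:01": {-17: "T", 9: "W", 11: "P", 13: "R", 26: "I", 28: "Q",
                   30: "V", 32: "F", 47: "A", 71: "A", 140: "S", 152: "A"},
}


def dr4_cluster_names() -> list[AlleleName]:
    return [parse_allele_name(n) for n in _FIXTURE_OVERRIDES if n.startswith("DRB1*04:")]


def dr4_fixture_catalog() -> AlleleCatalog:
    """The synthetic DR4 fixture catalog (see module docstring)."""
    positions = positions_from_indices(FIXTURE_POSITION_INDICES)
    alleles = {}
    for name, overrides in _FIXTURE_OVERRIDES.items():
        seq = "".join(
            overrides.get(p.index, _BACKBONE[p.index]) for p in positions
        )
        alleles[parse_allele_name(name)] = seq
    return AlleleCatalog(positions=positions, alleles=alleles)


#: chromosome copies per fixture allele: (case copies, control copies).
#: Every DR4 allele except 04:06 has >= 3 copies overall; 04:06 appears once
#: (the rare KAV motif).  Case counts skew toward the risk motifs.
_FIXTURE_COPIES: dict[str, tuple[int, int]] = {
    "DRB1*04:01": (20, 6),
    "DRB1*04:02": (3, 2),
    "DRB1*04:03": (1, 4),
    "DRB1*04:04": (8, 5),
    "DRB1*04:05": (4, 1),
    "DRB1*04:06": (1, 0),
    "DRB1*04:07": (1, 4),
    "DRB1*04:08": (3, 3),
    "DRB1*04:10": (2, 2),
    "DRB1*04:13": (2, 1),
    "DRB1*03:01": (10, 14),
    "DRB1*03:02": (4, 6),
    "DRB1*01:01": (6, 10),
    "DRB1*07:01": (4, 8),
    "DRB1*08:01": (2, 4),
    "DRB1*15:01": (5, 12),
}

#: deterministic DR->DQ haplotype assignment used by the fixture roster
_DQ_MAP: dict[str, tuple[str, str]] = {
    "DRB1*04:01": ("DQA1*03:01", "DQB1*03:02"),
    "DRB1*04:02": ("DQA1*03:01", "DQB1*03:02"),
    "DRB1*04:03": ("DQA1*03:01", "DQB1*03:02"),
    "DRB1*04:04": ("DQA1*03:01", "DQB1*03:02"),
    "DRB1*04:05": ("DQA1*03:01", "DQB1*03:02"),
    "DRB1*04:06": ("DQA1*03:01", "DQB1*03:02"),
    "DRB1*04:07": ("DQA1*03:03", "DQB1*03:01"),
    "DRB1*04:08": ("DQA1*03:03", "DQB1*03:01"),
    "DRB1*04:10": ("DQA1*03:01", "DQB1*03:02"),
    "DRB1*04:13": ("DQA1*03:03", "DQB1*03:01"),
    "DRB1*03:01": ("DQA1*05:01", "DQB1*02:01"),
    "DRB1*03:02": ("DQA1*05:01", "DQB1*02:01"),
    "DRB1*01:01": ("DQA1*01:01", "DQB1*05:01"),
    "DRB1*07:01": ("DQA1*02:01", "DQB1*02:02"),
    "DRB1*08:01": ("DQA1*04:01", "DQB1*04:02"),
    "DRB1*15:01": ("DQA1*01:02", "DQB1*06:02"),
}


def dr4_fixture_subjects(with_dq: bool = False) -> list[SubjectCC]:
    """Deterministic case-control roster realizing the fixture copy counts.

    Chromosomes are paired in a fixed interleaved order within each group,
    so the roster (and hence every downstream count) is reproducible without
    randomness.  38 cases and 41 controls.
    """
    subjects: list[SubjectCC] = []
    for y in (1, 0):
        chroms: list[str] = []
        for name, (ncase, nctrl) in _FIXTURE_COPIES.items():
            chroms.extend([name] * (ncase if y else nctrl))
        # interleave front/back so pairs mix alleles deterministically
        if len(chroms) % 2:
            raise AssertionError("fixture copies must pair into subjects")
        half = len(chroms) // 2
        front, back = chroms[:half], chroms[half:][::-1]
        for i, (a, b) in enumerate(zip(front, back)):
            name_a, name_b = parse_allele_name(a), parse_allele_name(b)
            kw = {}
            if with_dq:
                dq_a, dq_b = _DQ_MAP[a], _DQ_MAP[b]
                kw = {
                    "dqa1": (parse_allele_name(dq_a[0]), parse_allele_name(dq_b[0])),
                    "dqb1": (parse_allele_name(dq_a[1]), parse_allele_name(dq_b[1])),
                }
            subjects.append(
                SubjectCC(
                    id=f"{'case' if y else 'ctrl'}{i:03d}",
                    y=y,
                    drb1=(name_a, name_b),
                    **kw,
                )
            )
    return subjects


def make_allele_pool(
    n_cluster_alleles: int,
    n_outgroup_alleles: int,
    positions: Sequence[ResiduePosition],
    motif_table: Optional[Mapping[str, str]] = None,
    seed: int = 0,
    screen_positions: Optional[Sequence[ResiduePosition]] = None,
    preset: Optional[str] = None,
) -> AlleleCatalog:
    """Generate a catalog with one planted cluster and scattered outgroups.

    Cluster alleles share a random backbone and differ only at the screening
    positions, where ``motif_table`` (allele suffix -> residue string)
    assigns their residues; outgroup alleles are resampled at a large
    fraction of positions so every cluster pair is mutually closer than any
    cluster-outgroup pair.  ``preset="dr4"`` returns the packaged fixture.
    """
    if preset == "dr4":
        return dr4_fixture_catalog()
    if preset is not None:
        raise ValueError(f"unknown preset {preset!r}")
    rng = np.random.default_rng(seed)
    positions = tuple(positions)
    screen_positions = tuple(screen_positions or ())
    screen_idx = [positions.index(p) for p in screen_positions]
    backbone = rng.choice(list(AA), size=len(positions))
    alleles: dict[AlleleName, str] = {}
    motif_items = list((motif_table or {}).items())
    for k in range(n_cluster_alleles):
        seq = backbone.copy()
        if motif_items:
            suffix, residues = motif_items[k % len(motif_items)]
            if len(residues) != len(screen_idx):
                raise ValueError(
                    f"motif {residues!r} length != {len(screen_idx)} screen positions"
                )
            for i, aa in zip(screen_idx, residues):
                seq[i] = aa
            name = parse_allele_name(f"CL*{1:02d}:{k + 1:02d}")
        else:
            name = parse_allele_name(f"CL*{1:02d}:{k + 1:02d}")
        alleles[name] = "".join(seq)
    n_flip = max(len(positions) // 2, len(screen_idx) + 1)
    for k in range(n_outgroup_alleles):
        seq = backbone.copy()
        flip = rng.choice(len(positions), size=n_flip, replace=False)
        for i in flip:
            choices = [c for c in AA if c != seq[i]]
            seq[i] = choices[rng.integers(len(choices))]
        alleles[parse_allele_name(f"OG*{k + 2:02d}:01")] = "".join(seq)
    return AlleleCatalog(positions=positions, alleles=alleles)


# ---------------------------------------------------------------------------
# case-control simulator

EffectSpec = Union[float, tuple]

#: Swedish-population-like control allele frequencies for the fixture pool
DEFAULT_CC_FREQS: dict[str, float] = {
    "DRB1*04:01": 0.12, "DRB1*04:02": 0.01, "DRB1*04:03": 0.01,
    "DRB1*04:04": 0.04, "DRB1*04:05": 0.005, "DRB1*04:06": 0.002,
    "DRB1*04:07": 0.005, "DRB1*04:08": 0.005, "DRB1*04:10": 0.003,
    "DRB1*04:13": 0.01, "DRB1*03:01": 0.16, "DRB1*03:02": 0.01,
    "DRB1*01:01": 0.10, "DRB1*07:01": 0.12, "DRB1*08:01": 0.06,
    "DRB1*15:01": 0.34,
}


def _effect_eta(copies: np.ndarray, spec: EffectSpec) -> np.ndarray:
    """Linear-predictor contribution of one category's chromosome copies.

    A bare float is a per-copy (log-additive) effect; ``("carriage", v)``
    applies v to carriers of >= 1 copy; ``("genotype", het, hom)`` codes the
    heterozygote and homozygote separately.
    """
    if isinstance(spec, (int, float)):
        return copies * float(spec)
    kind = spec[0]
    if kind == "carriage":
        return np.where(copies >= 1, float(spec[1]), 0.0)
    if kind == "genotype":
        return np.where(copies == 2, float(spec[2]),
                        np.where(copies == 1, float(spec[1]), 0.0))
    raise ValueError(f"unknown effect spec {spec!r}")


@dataclass
class SimConfigCC:
    """Case-control simulation: logistic disease model over motif copies."""

    allele_freqs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CC_FREQS)
    )
    effects: Mapping[str, EffectSpec] = field(default_factory=dict)
    baseline: float = -4.0
    n_case: int = 500
    n_ctrl: int = 500
    seed: int = 0
    catalog: Optional[AlleleCatalog] = None
    motif_positions: Optional[Sequence[ResiduePosition]] = None
    antibody_models: Mapping[str, tuple[float, Mapping[str, EffectSpec]]] = field(
        default_factory=dict
    )
    dq_map: Optional[Mapping[str, tuple[str, str]]] = None

    def __post_init__(self) -> None:
        total = sum(self.allele_freqs.values())
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"allele frequencies sum to {total}, not 1")
        if self.n_case < 1 or self.n_ctrl < 1:
            raise ValueError("need positive case and control targets")


@dataclass
class SimCCResult:
    subjects: list[SubjectCC]
    truth: pd.DataFrame  # latent per-subject linear predictors; not for analysis


def _category_of_alleles(cfg) -> dict[str, str]:
    """Allele canonical name -> effect category (motif when a catalog is
    given, else the allele name itself)."""
    out = {}
    for name in cfg.allele_freqs:
        if cfg.catalog is not None and cfg.motif_positions is not None:
            out[name] = motif_of(
                cfg.catalog, parse_allele_name(name), cfg.motif_positions
            ).residues
        else:
            out[name] = name
    return out


def simulate_case_control(cfg: SimConfigCC) -> SimCCResult:
    """Rejection-sample a case-control study from the logistic model.

    Genotypes are two independent draws from the frequency vector;
    ``P(y=1) = logistic(baseline + sum of category effects)``; sampling
    continues until both the case and control targets are met (matching a
    design where the two arms are recruited separately).  Antibody flags for
    patients are generated from per-antibody logistic models when
    configured.
    """
    rng = np.random.default_rng(cfg.seed)
    names = list(cfg.allele_freqs)
    freqs = np.array([cfg.allele_freqs[n] for n in names])
    cat_of = _category_of_alleles(cfg)
    categories = sorted(set(cat_of.values()))
    cat_idx = np.array([categories.index(cat_of[n]) for n in names])
    eff_cats = [c for c in categories if c in cfg.effects]
    if set(cfg.effects) - set(categories):
        raise ValueError(
            f"effects reference unknown categories: "
            f"{sorted(set(cfg.effects) - set(categories))}"
        )

    max_eta = cfg.baseline + sum(
        max(np.max(_effect_eta(np.array([0, 1, 2]), cfg.effects[c])), 0)
        for c in eff_cats
    )
    if 1.0 / (1.0 + math.exp(-max_eta)) <= 0:  # pragma: no cover - guard
        raise ValueError("case probability is zero everywhere")

    got_case = got_ctrl = 0
    keep_a1, keep_a2, keep_y, keep_eta = [], [], [], []
    batch = max(4 * (cfg.n_case + cfg.n_ctrl), 10_000)
    guard = 0
    while got_case < cfg.n_case or got_ctrl < cfg.n_ctrl:
        guard += 1
        if guard > 2000:
            raise RuntimeError("rejection sampling failed to reach group targets")
        a1 = rng.choice(len(names), size=batch, p=freqs)
        a2 = rng.choice(len(names), size=batch, p=freqs)
        eta = np.full(batch, cfg.baseline)
        for c in eff_cats:
            ci = categories.index(c)
            copies = (cat_idx[a1] == ci).astype(int) + (cat_idx[a2] == ci).astype(int)
            eta += _effect_eta(copies, cfg.effects[c])
        y = (rng.random(batch) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
        need_case = cfg.n_case - got_case
        need_ctrl = cfg.n_ctrl - got_ctrl
        case_sel = np.flatnonzero(y == 1)[:need_case]
        ctrl_sel = np.flatnonzero(y == 0)[:need_ctrl]
        sel = np.sort(np.concatenate([case_sel, ctrl_sel]))
        keep_a1.append(a1[sel]); keep_a2.append(a2[sel])
        keep_y.append(y[sel]); keep_eta.append(eta[sel])
        got_case += len(case_sel); got_ctrl += len(ctrl_sel)

    a1 = np.concatenate(keep_a1); a2 = np.concatenate(keep_a2)
    y = np.concatenate(keep_y); eta = np.concatenate(keep_eta)

    subjects: list[SubjectCC] = []
    rows = []
    for i in range(len(y)):
        n1, n2 = names[a1[i]], names[a2[i]]
        antibodies: dict[str, int] = {}
        if y[i] == 1 and cfg.antibody_models:
            for ab, (ab_base, ab_eff) in cfg.antibody_models.items():
                ab_eta = ab_base
                for c, spec in ab_eff.items():
                    copies = int(cat_of[n1] == c) + int(cat_of[n2] == c)
                    ab_eta += float(_effect_eta(np.array([copies]), spec)[0])
                antibodies[ab] = int(rng.random() < 1.0 / (1.0 + math.exp(-ab_eta)))
        kw = {}
        if cfg.dq_map is not None:
            dq1, dq2 = cfg.dq_map[n1], cfg.dq_map[n2]
            kw = {
                "dqa1": (parse_allele_name(dq1[0]), parse_allele_name(dq2[0])),
                "dqb1": (parse_allele_name(dq1[1]), parse_allele_name(dq2[1])),
            }
        subjects.append(
            SubjectCC(
                id=f"sim{i:06d}", y=int(y[i]),
                drb1=(parse_allele_name(n1), parse_allele_name(n2)),
                antibodies=antibodies, **kw,
            )
        )
        rows.append({"id": subjects[-1].id, "allele1": n1, "allele2": n2,
                     "eta": float(eta[i]), "y": int(y[i])})
    return SimCCResult(subjects=subjects, truth=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# birth-cohort simulator

#: risk-enriched (cohort-ascertainment-like) allele frequencies
DEFAULT_COHORT_FREQS: dict[str, float] = {
    "DRB1*04:01": 0.25, "DRB1*04:02": 0.02, "DRB1*04:03": 0.01,
    "DRB1*04:04": 0.08, "DRB1*04:05": 0.02, "DRB1*04:07": 0.01,
    "DRB1*04:08": 0.01, "DRB1*03:01": 0.30, "DRB1*03:02": 0.05,
    "DRB1*01:01": 0.10, "DRB1*07:01": 0.06, "DRB1*08:01": 0.04,
    "DRB1*15:01": 0.05,
}


def default_visit_schedule(
    early_interval: float = 0.25,
    switch_age: float = 4.0,
    late_interval: float = 0.5,
    horizon: float = 10.0,
) -> np.ndarray:
    """Quarterly visits to age four, semiannual thereafter."""
    early = np.arange(early_interval, switch_age + 1e-9, early_interval)
    late = np.arange(switch_age + late_interval, horizon + 1e-9, late_interval)
    return np.concatenate([early, late])


@dataclass
class SimConfigCohort:
    """Birth-cohort simulation: Weibull hazards seen through visit panels."""

    n: int = 1000
    allele_freqs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COHORT_FREQS)
    )
    effects: Mapping[str, EffectSpec] = field(
        default_factory=lambda: {"KAG": ("carriage", math.log(1.74))}
    )
    #: per-antibody Weibull baseline (scale in years, shape)
    weibull: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "GADA": (180.0, 0.8), "IAA": (220.0, 0.7), "IA2A": (350.0, 1.0)
        }
    )
    thresholds: Mapping[str, float] = field(
        default_factory=lambda: {ab: 1.0 for ab in ANTIBODIES}
    )
    sex_effect: float = 0.1
    family_history_effect: float = 0.4
    family_history_prev: float = 0.10
    location_effects: Sequence[float] = (0.0, 0.1, -0.1, 0.05)
    dropout_rate: float = 0.02
    horizon: float = 10.0
    exceedance: float = 0.25
    noise_sd: float = 0.5
    seed: int = 0
    catalog: Optional[AlleleCatalog] = None
    motif_positions: Optional[Sequence[ResiduePosition]] = None
    visit_schedule: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        total = sum(self.allele_freqs.values())
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"allele frequencies sum to {total}, not 1")
        for ab, (scale, shape) in self.weibull.items():
            if scale <= 0 or shape <= 0:
                raise ValueError(f"{ab}: Weibull scale/shape must be positive")
        sched = (
            np.asarray(self.visit_schedule, dtype=float)
            if self.visit_schedule is not None
            else default_visit_schedule(horizon=self.horizon)
        )
        if np.any(np.diff(sched) <= 0):
            raise ValueError("visit schedule must be strictly increasing")
        self.visit_schedule = sched


@dataclass
class SimCohortResult:
    subjects: list[SubjectCohort]
    truth: pd.DataFrame  # latent event times and predictors; not for analysis


def simulate_cohort(cfg: SimConfigCohort) -> SimCohortResult:
    """Simulate antibody panels under Weibull proportional hazards.

    Each antibody has a latent event time drawn from its Weibull baseline
    scaled by ``exp(eta)`` for the subject's genetic and demographic linear
    predictor.  Measured values sit below threshold before the latent time
    and above it afterwards (log-normal spread around a fixed exceedance
    margin), evaluated at the scheduled visits; follow-up ends at the
    horizon or an exponential dropout time.  The first visit at or after the
    latent time is therefore the observed crossing visit.
    """
    rng = np.random.default_rng(cfg.seed)
    names = list(cfg.allele_freqs)
    freqs = np.array([cfg.allele_freqs[n] for n in names])
    cat_of = _category_of_alleles(cfg)
    categories = sorted(set(cat_of.values()))
    cat_idx = np.array([categories.index(cat_of[n]) for n in names])

    n = cfg.n
    a1 = rng.choice(len(names), size=n, p=freqs)
    a2 = rng.choice(len(names), size=n, p=freqs)
    sex = rng.integers(0, 2, size=n)
    fam = (rng.random(n) < cfg.family_history_prev).astype(int)
    loc = rng.integers(0, len(cfg.location_effects), size=n)

    eta = (
        cfg.sex_effect * sex
        + cfg.family_history_effect * fam
        + np.asarray(cfg.location_effects)[loc]
    )
    for c, spec in cfg.effects.items():
        if c not in categories:
            raise ValueError(f"effect category {c!r} not produced by the pool")
        ci = categories.index(c)
        copies = (cat_idx[a1] == ci).astype(int) + (cat_idx[a2] == ci).astype(int)
        eta = eta + _effect_eta(copies, spec)

    sched = cfg.visit_schedule
    dropout = (
        rng.exponential(1.0 / cfg.dropout_rate, size=n)
        if cfg.dropout_rate > 0
        else np.full(n, np.inf)
    )
    censor = np.minimum(cfg.horizon, dropout)
    censor = np.maximum(censor, sched[0])  # at least one visit of follow-up

    latent: dict[str, np.ndarray] = {}
    for ab, (scale, shape) in cfg.weibull.items():
        e = rng.exponential(1.0, size=n)
        latent[ab] = scale * (e / np.exp(eta)) ** (1.0 / shape)

    # value matrices are built in one vectorized pass and sliced per subject
    n_vis = np.searchsorted(sched, censor, side="right")
    value_mat: dict[str, np.ndarray] = {}
    for ab in ANTIBODIES:
        spread = cfg.exceedance + np.abs(
            rng.normal(0.0, cfg.noise_sd, size=(n, sched.size))
        )
        above = sched[None, :] >= latent[ab][:, None]
        value_mat[ab] = cfg.thresholds[ab] * np.exp(np.where(above, spread, -spread))

    subjects: list[SubjectCohort] = []
    rows = []
    for i in range(n):
        k = max(int(n_vis[i]), 1)
        visits = sched[:k]
        values = {ab: value_mat[ab][i, :k] for ab in ANTIBODIES}
        panel = AntibodyPanel(
            subject_id=f"ch{i:06d}",
            visits=visits,
            values=values,
            thresholds=dict(cfg.thresholds),
            last_contact=float(visits[-1]),
        )
        subjects.append(
            SubjectCohort(
                id=panel.subject_id,
                drb1=(parse_allele_name(names[a1[i]]),
                      parse_allele_name(names[a2[i]])),
                covariates={
                    "sex": int(sex[i]),
                    "family_history": int(fam[i]),
                    "location": f"site{loc[i] + 1}",
                },
                panel=panel,
            )
        )
        rows.append(
            {"id": panel.subject_id, "eta": float(eta[i]),
             "censor": float(censor[i]),
             **{f"latent_{ab}": float(latent[ab][i]) for ab in ANTIBODIES}}
        )
    return SimCohortResult(subjects=subjects, truth=pd.DataFrame(rows))
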