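"""Seroconversion endpoints and time-to-event association (HOH validation arm).

A birth cohort measures islet autoantibodies (GADA, IAA, IA-2A) on a visit
schedule.  Five endpoints are derived per child: antibody-specific
seroconversion (first visit at which that antibody exceeds its threshold),
overall seroconversion (earliest antibody-specific event), and double
seroconversion (the time at which a second antibody has ever crossed its
threshold, i.e. the second order statistic of the antibody-specific times).
Children without an event are censored at last contact.

Association uses Kaplan-Meier incidence, log-rank contrasts, and Cox
proportional-hazards models: univariate one-vs-rest fits (carriage of one
category versus all others combined), a multivariable fit against a chosen
reference group, and a genotype dose-response coding (0/1/2 copies).  The
partial likelihood is maximized by Newton iterations with Efron handling of
the heavy ties that a visit schedule produces; proportionality is checked
with the Grambsch-Therneau scaled-Schoenfeld diagnostic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import AlleleName

logger = logging.getLogger(__name__)

__all__ = [
    "ANTIBODIES",
    "DEFINITIONS",
    "AntibodyPanel",
    "EventOutcome",
    "SubjectCohort",
    "CoxResult",
    "CoxFit",
    "PHDiagnostic",
    "KMCurve",
    "derive_seroconversion",
    "derive_all_definitions",
    "km_incidence",
    "logrank_test",
    "cox_fit",
    "cox_one_vs_rest",
    "cox_multivar_reference",
    "genotype_dose_assoc",
    "ph_diagnostic",
    "read_panels_tsv",
    "write_panels_tsv",
    "write_outcomes_tsv",
]

ANTIBODIES = ("GADA", "IAA", "IA2A")
DEFINITIONS = ("overall", "double", "GADA", "IAA", "IA2A")

#: the standard adjusters: sex, family history, and study site
DEFAULT_ADJUSTERS = ("sex", "family_history", "location")


# ---------------------------------------------------------------------------
# endpoint construction


@dataclass
class AntibodyPanel:
    """Longitudinal autoantibody measurements for one subject."""

    subject_id: str
    visits: np.ndarray  # strictly increasing times in years
    values: dict[str, np.ndarray]  # per antibody, aligned to visits
    thresholds: dict[str, float]
    last_contact: float

    def __post_init__(self) -> None:
        self.visits = np.asarray(self.visits, dtype=float)
        if self.visits.size and np.any(np.diff(self.visits) <= 0):
            raise ValueError(f"{self.subject_id}: visits not strictly increasing")
        for ab, v in self.values.items():
            v = np.asarray(v, dtype=float)
            self.values[ab] = v
            if v.shape != self.visits.shape:
                raise ValueError(f"{self.subject_id}: {ab} series length mismatch")
        for ab, thr in self.thresholds.items():
            if not math.isfinite(thr):
                raise ValueError(f"{self.subject_id}: non-finite threshold for {ab}")


@dataclass(frozen=True)
class EventOutcome:
    """(time, event) under one seroconversion definition."""

    subject_id: str
    definition: str
    time: float
    event: int

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"{self.subject_id}: nonpositive outcome time")
        if self.event not in (0, 1):
            raise ValueError("event indicator must be 0 or 1")


@dataclass
class SubjectCohort:
    """Cohort subject: genotype, the three adjusters, and the antibody panel."""

    id: str
    drb1: tuple[AlleleName, AlleleName]
    covariates: dict[str, object]
    panel: AntibodyPanel

    def __post_init__(self) -> None:
        missing = [k for k in DEFAULT_ADJUSTERS if k not in self.covariates]
        if missing:
            raise ValueError(f"subject {self.id}: missing covariates {missing}")


def _first_crossing(panel: AntibodyPanel, antibody: str) -> Optional[float]:
    """Time of the first visit at which the antibody strictly exceeds its
    threshold, or None if it never does."""
    above = panel.values[antibody] > panel.thresholds[antibody]
    idx = np.flatnonzero(above)
    return float(panel.visits[idx[0]]) if idx.size else None


def derive_seroconversion(panel: AntibodyPanel, definition: str) -> EventOutcome:
    """Build the (time, event) outcome for one seroconversion definition.

    ``overall`` is the earliest antibody-specific crossing; ``double`` is
    the time at which a second distinct antibody has ever crossed (the
    second order statistic of the antibody-specific times).  Crossing is
    strict (value > threshold) and the event time is the visit time itself.
    No qualifying visit means censoring at last contact.
    """
    if panel.visits.size == 0:
        raise ValueError(f"{panel.subject_id}: empty visit list")
    if definition not in DEFINITIONS:
        raise ValueError(f"unknown definition {definition!r}")
    if definition in ANTIBODIES:
        t = _first_crossing(panel, definition)
    else:
        times = sorted(
            t for ab in ANTIBODIES
            if (t := _first_crossing(panel, ab)) is not None
        )
        if definition == "overall":
            t = times[0] if times else None
        else:  # double
            t = times[1] if len(times) >= 2 else None
    if t is None:
        return EventOutcome(panel.subject_id, definition, panel.last_contact, 0)
    return EventOutcome(panel.subject_id, definition, t, 1)


def derive_all_definitions(panel: AntibodyPanel) -> dict[str, EventOutcome]:
    return {d: derive_seroconversion(panel, d) for d in DEFINITIONS}


# ---------------------------------------------------------------------------
# Kaplan-Meier incidence and log-rank


@dataclass
class KMCurve:
    """Right-continuous cumulative-incidence step function, 1 - KM survival."""

    times: np.ndarray
    incidence: np.ndarray

    def __call__(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 0.0 if idx < 0 else float(self.incidence[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "incidence": self.incidence})


def km_incidence(outcomes: Sequence[EventOutcome]) -> KMCurve:
    """Product-limit cumulative incidence with jumps at event times."""
    if not outcomes:
        raise ValueError("need at least one outcome")
    from lifelines import KaplanMeierFitter

    t = np.array([o.time for o in outcomes])
    e = np.array([o.event for o in outcomes])
    km = KaplanMeierFitter().fit(t, e)
    surv = km.survival_function_["KM_estimate"]
    times = surv.index.to_numpy(dtype=float)
    inc = 1.0 - surv.to_numpy(dtype=float)
    keep = times > 0  # drop the t=0 anchor row; incidence(0)=0 is implicit
    return KMCurve(times=times[keep], incidence=inc[keep])


def logrank_test(
    outcomes: Sequence[EventOutcome], groups: Sequence[str]
) -> tuple[float, float]:
    """Standard log-rank chi-square across groups (df = #groups - 1)."""
    if len(outcomes) != len(groups):
        raise ValueError("outcomes and group labels differ in length")
    uniq = sorted(set(groups))
    if len(uniq) < 2:
        raise ValueError("need at least two nonempty groups")
    from lifelines.statistics import multivariate_logrank_test

    res = multivariate_logrank_test(
        np.array([o.time for o in outcomes]),
        np.asarray(groups),
        np.array([o.event for o in outcomes]),
    )
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Cox partial likelihood (Newton, Efron ties)


class CoxSeparationError(RuntimeError):
    """Monotone partial likelihood: a coefficient is diverging."""


@dataclass
class CoxResult:
    """One model term: coefficient, hazard ratio, SE, Z, two-sided p."""

    term: str
    coef: float
    SE: float

    @property
    def HR(self) -> float:
        return math.exp(self.coef)

    @property
    def Z(self) -> float:
        return self.coef / self.SE

    @property
    def p(self) -> float:
        return float(2.0 * stats.norm.sf(abs(self.Z)))


@dataclass
class CoxFit:
    """A fitted Cox model plus the ingredients diagnostics need."""

    results: list[CoxResult]
    terms: list[str]
    beta: np.ndarray
    information: np.ndarray  # observed information at beta
    loglik: float
    durations: np.ndarray
    events: np.ndarray
    design: np.ndarray
    ties: str
    n_iter: int

    def __iter__(self):
        return iter(self.results)

    def __len__(self) -> int:
        return len(self.results)

    def __getitem__(self, term: str) -> CoxResult:
        return self.results[self.terms.index(term)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"term": r.term, "coef": r.coef, "HR": r.HR,
                 "SE": r.SE, "Z": r.Z, "p": r.p}
                for r in self.results
            ]
        )


def _cox_quantities(
    beta: np.ndarray,
    t: np.ndarray,
    e: np.ndarray,
    X: np.ndarray,
    ties: str,
    want_hessian: bool = True,
    want_residuals: bool = False,
):
    """Log partial likelihood, gradient, Hessian (and Schoenfeld residuals).

    Inputs must be sorted by ascending duration.  Efron tie handling
    subtracts the fraction l/d of the tied-set sums from the risk-set sums
    for the l-th of d tied events; Breslow uses the plain risk-set sums.
    """
    n, p = X.shape
    eta = X @ beta
    eta = np.clip(eta, -700, 700)
    w = np.exp(eta)
    wx = w[:, None] * X
    # suffix sums over the risk set {j : t_j >= t}
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wx[::-1], axis=0)[::-1]
    if want_hessian:
        wxx = wx[:, :, None] * X[:, None, :]
        S2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    loglik = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    resid = np.zeros((int(e.sum()), p)) if want_residuals else None
    resid_times = np.zeros(int(e.sum())) if want_residuals else None
    r_at = 0

    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        D = [k for k in range(i, j) if e[k] == 1]
        d = len(D)
        if d:
            D0 = w[D].sum()
            D1 = wx[D].sum(axis=0)
            frac = (np.arange(d) / d) if ties == "efron" else np.zeros(d)
            phi = S0[i] - frac * D0  # (d,)
            mu = (S1[i][None, :] - frac[:, None] * D1[None, :]) / phi[:, None]
            loglik += float(eta[D].sum() - np.log(phi).sum())
            grad += X[D].sum(axis=0) - mu.sum(axis=0)
            if want_hessian:
                D2 = wxx[D].sum(axis=0)
                inv_phi = (1.0 / phi).sum()
                frac_phi = (frac / phi).sum()
                hess -= S2[i] * inv_phi - D2 * frac_phi - mu.T @ mu
            if want_residuals:
                for l, k in enumerate(D):
                    resid[r_at] = X[k] - mu[min(l, d - 1)]
                    resid_times[r_at] = t[k]
                    r_at += 1
        i = j
    out = [loglik, grad]
    if want_hessian:
        out.append(hess)
    if want_residuals:
        out.extend([resid, resid_times])
    return tuple(out)


def cox_fit(
    outcomes: Sequence[EventOutcome],
    design: pd.DataFrame,
    ties: str = "efron",
    max_iter: int = 50,
    score_tol: float = 1e-8,
) -> CoxFit:
    """Maximize the Cox partial likelihood by Newton iterations.

    ``design`` holds one numeric column per model term, row-aligned with
    ``outcomes``.  Convergence requires ``max |score| < 1e-8``; ties are
    handled with the Efron correction by default.  An empty design returns
    an empty fit.

    Raises
    ------
    CoxSeparationError
        When the likelihood is monotone in some coefficient (the message
        names the term).
    RuntimeError
        If Newton fails to converge within ``max_iter`` iterations.
    ValueError
        With no events or a rank-deficient design.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie method {ties!r}")
    terms = list(design.columns)
    t = np.array([o.time for o in outcomes], dtype=float)
    e = np.array([o.event for o in outcomes], dtype=int)
    if len(design) != len(t):
        raise ValueError("design and outcomes differ in length")
    if not terms:
        return CoxFit([], [], np.zeros(0), np.zeros((0, 0)), 0.0,
                      t, e, np.zeros((len(t), 0)), ties, 0)
    if e.sum() == 0:
        raise ValueError("no events")
    X = design.to_numpy(dtype=float)
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < X.shape[1]:
        raise ValueError("design is not full rank")
    order = np.argsort(t, kind="stable")
    t, e, X = t[order], e[order], X[order]

    beta = np.zeros(X.shape[1])
    loglik, grad, hess = _cox_quantities(beta, t, e, X, ties)
    for it in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < score_tol:
            if np.max(np.abs(beta)) > 10:
                # the score can dip under tolerance while drifting to an
                # infinite optimum; a log-hazard beyond 10 is that signature
                worst = terms[int(np.argmax(np.abs(beta)))]
                raise CoxSeparationError(
                    f"monotone likelihood: coefficient for {worst!r} diverges"
                )
            info = -hess
            try:
                cov = np.linalg.inv(info)
            except np.linalg.LinAlgError as err:
                raise CoxSeparationError(
                    "information matrix singular at the optimum "
                    f"(term {terms[int(np.argmax(np.abs(beta)))]!r})"
                ) from err
            if np.any(np.diag(cov) <= 0) or not np.all(np.isfinite(cov)):
                raise CoxSeparationError("information matrix not positive definite")
            se = np.sqrt(np.diag(cov))
            results = [
                CoxResult(term=terms[k], coef=float(beta[k]), SE=float(se[k]))
                for k in range(len(terms))
            ]
            return CoxFit(results, terms, beta, info, loglik, t, e, X, ties, it - 1)
        try:
            step = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError as err:
            raise CoxSeparationError(
                f"singular information (term {terms[int(np.argmax(np.abs(grad)))]})"
            ) from err
        # step-halving to keep the likelihood nondecreasing; the tolerance
        # is relative so rounding noise at the optimum cannot stall it
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            new_ll, new_grad, new_hess = _cox_quantities(cand, t, e, X, ties)
            if new_ll >= loglik - 1e-10 * (1.0 + abs(loglik)):
                break
            scale *= 0.5
        beta, loglik, grad, hess = cand, new_ll, new_grad, new_hess
        if np.max(np.abs(beta)) > 20:
            worst = terms[int(np.argmax(np.abs(beta)))]
            raise CoxSeparationError(
                f"monotone likelihood: coefficient for {worst!r} diverges"
            )
    raise RuntimeError(f"Cox fit did not converge in {max_iter} iterations")


# ---------------------------------------------------------------------------
# model builders


def _adjuster_frame(
    cohort: Sequence[SubjectCohort], adjusters: Sequence[str]
) -> pd.DataFrame:
    """Numeric adjuster columns; categoricals (location) are dummy-coded
    against their first level."""
    cols: dict[str, np.ndarray] = {}
    for name in adjusters:
        vals = [s.covariates[name] for s in cohort]
        if all(isinstance(v, (int, float, np.integer, np.floating)) for v in vals):
            cols[name] = np.asarray(vals, dtype=float)
        else:
            levels = sorted({str(v) for v in vals})
            for lev in levels[1:]:
                cols[f"{name}[{lev}]"] = np.array(
                    [1.0 if str(v) == lev else 0.0 for v in vals]
                )
    return pd.DataFrame(cols)


def _carriage_copies(
    subject: SubjectCohort, mapper: Callable[[AlleleName], Optional[str]], category: str
) -> int:
    return sum(1 for a in subject.drb1 if mapper(a) == category)


def cox_one_vs_rest(
    cohort: Sequence[SubjectCohort],
    mapper: Callable[[AlleleName], Optional[str]],
    definition: str,
    adjusters: Sequence[str] = DEFAULT_ADJUSTERS,
    categories: Optional[Sequence[str]] = None,
    ties: str = "efron",
) -> dict[str, CoxFit]:
    """Univariate one-vs-rest Cox fit per category.

    For each category the model term is a carriage indicator (subject
    carries >= 1 chromosome of that category) against everyone else, with
    the adjusters alongside.  Returns the full fit per category; the
    category's own term is ``fit[category]``.
    """
    outcomes = [derive_seroconversion(s.panel, definition) for s in cohort]
    adj = _adjuster_frame(cohort, adjusters)
    observed = sorted(
        {c for s in cohort for a in s.drb1 if (c := mapper(a)) is not None}
    )
    cats = list(categories) if categories is not None else observed
    fits: dict[str, CoxFit] = {}
    for cat in cats:
        carrier = np.array(
            [1.0 if _carriage_copies(s, mapper, cat) >= 1 else 0.0 for s in cohort]
        )
        if carrier.sum() == 0:
            raise ValueError(f"category {cat!r} carried by nobody")
        design = pd.concat(
            [pd.DataFrame({cat: carrier}), adj.reset_index(drop=True)], axis=1
        )
        fits[cat] = cox_fit(outcomes, design, ties=ties)
    return fits


def cox_multivar_reference(
    cohort: Sequence[SubjectCohort],
    groups: Mapping[str, set[str]],
    reference: str,
    mapper: Callable[[AlleleName], Optional[str]],
    definition: str,
    adjusters: Sequence[str] = DEFAULT_ADJUSTERS,
    ties: str = "efron",
) -> CoxFit:
    """Single multivariable fit: one carriage indicator per non-reference
    motif group, with the reference group absorbed into the baseline."""
    if reference not in groups:
        raise KeyError(f"reference group {reference!r} not among groups")
    outcomes = [derive_seroconversion(s.panel, definition) for s in cohort]
    adj = _adjuster_frame(cohort, adjusters)
    cols: dict[str, np.ndarray] = {}
    for name, members in groups.items():
        if name == reference:
            continue
        cols[name] = np.array(
            [
                1.0 if any(mapper(a) in members for a in s.drb1) else 0.0
                for s in cohort
            ]
        )
    if not cols:
        return cox_fit(outcomes, pd.DataFrame(index=range(len(cohort))), ties=ties)
    design = pd.concat(
        [pd.DataFrame(cols), adj.reset_index(drop=True)], axis=1
    )
    return cox_fit(outcomes, design, ties=ties)


def genotype_dose_assoc(
    cohort: Sequence[SubjectCohort],
    motif: str,
    mapper: Callable[[AlleleName], Optional[str]],
    definition: str,
    adjusters: Sequence[str] = DEFAULT_ADJUSTERS,
    ties: str = "efron",
) -> tuple[CoxFit, dict[str, KMCurve]]:
    """Genotype dose-response: heterozygote and homozygote indicators versus
    the zero-copy reference, plus per-genotype incidence curves.

    With no homozygotes in the cohort the homozygote term is omitted (and
    logged) rather than fit against an empty stratum.
    """
    outcomes = [derive_seroconversion(s.panel, definition) for s in cohort]
    copies = np.array([_carriage_copies(s, mapper, motif) for s in cohort])
    cols: dict[str, np.ndarray] = {}
    if (copies == 1).any():
        cols[f"{motif}/other"] = (copies == 1).astype(float)
    if (copies == 2).any():
        cols[f"{motif}/{motif}"] = (copies == 2).astype(float)
    else:
        logger.info("genotype_dose_assoc(%s): no homozygotes, term omitted", motif)
    adj = _adjuster_frame(cohort, adjusters)
    design = pd.concat([pd.DataFrame(cols), adj.reset_index(drop=True)], axis=1)
    fit = cox_fit(outcomes, design, ties=ties)
    labels = {0: "other/other", 1: f"{motif}/other", 2: f"{motif}/{motif}"}
    curves = {
        labels[k]: km_incidence([o for o, c in zip(outcomes, copies) if c == k])
        for k in sorted(set(copies.tolist()))
    }
    return fit, curves


# ---------------------------------------------------------------------------
# proportional-hazards diagnostic


@dataclass
class PHDiagnostic:
    """Grambsch-Therneau test: per-term and global chi-square."""

    terms: list[str]
    chi2: np.ndarray
    p: np.ndarray
    global_chi2: float
    global_p: float
    transform: str

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"term": self.terms, "chi2": self.chi2, "p": self.p})
        df.loc[len(df)] = ["GLOBAL", self.global_chi2, self.global_p]
        return df


def _transform_times(
    kind: str, event_times: np.ndarray, t: np.ndarray, e: np.ndarray
) -> np.ndarray:
    if kind == "identity":
        return event_times
    if kind == "log":
        return np.log(event_times)
    if kind == "rank":
        return stats.rankdata(event_times)
    if kind == "km":
        # left-continuous Kaplan-Meier survival of the whole sample at the
        # event times: g(t) = 1 - S(t-)
        from lifelines import KaplanMeierFitter

        km = KaplanMeierFitter().fit(t, e)
        surv = km.survival_function_["KM_estimate"]
        times = surv.index.to_numpy(dtype=float)
        vals = surv.to_numpy(dtype=float)
        idx = np.searchsorted(times, event_times, side="left") - 1
        s_minus = np.where(idx >= 0, vals[np.clip(idx, 0, None)], 1.0)
        return 1.0 - s_minus
    raise ValueError(f"unknown time transform {kind!r}")


def ph_diagnostic(fit: CoxFit, transform: str = "km") -> PHDiagnostic:
    """Grambsch-Therneau proportionality test on a fitted Cox model.

    Schoenfeld residuals at the fitted coefficients are paired with a
    transform g of the event times; with d events, information matrix I and
    u = sum_k (g_k - gbar) r_k, the global statistic is
    ``d * u' I^{-1} u / sum (g_k - gbar)^2`` on p degrees of freedom and the
    per-term statistic isolates one coordinate against its own variance.

    Raises
    ------
    ValueError
        With fewer than two events or an empty model.
    """
    if not fit.terms:
        raise ValueError("diagnostic needs a fitted term")
    d = int(fit.events.sum())
    if d < 2:
        raise ValueError("need at least two events for the diagnostic")
    _, _, resid, resid_t = _cox_quantities(
        fit.beta, fit.durations, fit.events, fit.design, fit.ties,
        want_hessian=False, want_residuals=True,
    )
    g = _transform_times(transform, resid_t, fit.durations, fit.events)
    g = g - g.mean()
    gg = float((g ** 2).sum())
    u = resid.T @ g
    inv_info = np.linalg.inv(fit.information)
    global_chi2 = float(d * u @ inv_info @ u / gg)
    global_p = float(stats.chi2.sf(global_chi2, df=len(fit.terms)))
    iu = inv_info @ u
    chi2 = d * iu ** 2 / (np.diag(inv_info) * gg)
    p = stats.chi2.sf(chi2, df=1)
    return PHDiagnostic(
        terms=list(fit.terms), chi2=chi2, p=p,
        global_chi2=global_chi2, global_p=global_p, transform=transform,
    )


# ---------------------------------------------------------------------------
# I/O


def write_panels_tsv(panels: Sequence[AntibodyPanel], path: str | Path) -> None:
    """Long-format panel table: id, visit_time, one column per antibody."""
    rows = []
    for p in panels:
        for i, t in enumerate(p.visits):
            row = {"id": p.subject_id, "visit_time": t}
            for ab in ANTIBODIES:
                row[ab] = p.values[ab][i]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_panels_tsv(
    path: str | Path,
    thresholds: Mapping[str, float],
    last_contact: Optional[Mapping[str, float]] = None,
) -> list[AntibodyPanel]:
    """Read long-format panels; last contact defaults to the last visit."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    panels = []
    for sid, sub in df.groupby("id", sort=True):
        sub = sub.sort_values("visit_time")
        visits = sub["visit_time"].to_numpy(dtype=float)
        lc = last_contact.get(sid) if last_contact else None
        panels.append(
            AntibodyPanel(
                subject_id=str(sid),
                visits=visits,
                values={ab: sub[ab].to_numpy(dtype=float) for ab in ANTIBODIES},
                thresholds=dict(thresholds),
                last_contact=float(lc) if lc is not None else float(visits[-1]),
            )
        )
    return panels


def write_outcomes_tsv(outcomes: Sequence[EventOutcome], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"id": o.subject_id, "definition": o.definition,
             "time": o.time, "event": o.event}
            for o in outcomes
        ]
    ).to_csv(path, sep="\t", index=False)
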