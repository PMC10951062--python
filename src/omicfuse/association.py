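"""Subgroup characterization: per-feature regression, endpoint, survival.

Each molecule is tested marginally with a covariate-adjusted logistic
regression (subgroup membership ~ feature + age + sex + BMI), p-values are
corrected with the Benjamini-Hochberg step-up procedure, glycaemic
deterioration is derived from longitudinal records as a composite
time-to-insulin endpoint, subgroup hazard ratios come from a Cox
proportional-hazards model, and agreement with external cluster labels is
scored by hypergeometric overlap enrichment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from scipy.stats import hypergeom

from .containers import OmicsBlock

__all__ = [
    "EndpointRules",
    "AssociationRow",
    "CoxResult",
    "logistic_per_feature",
    "bh_adjust",
    "derive_time_to_insulin",
    "cox_ph",
    "overlap_enrichment",
]

#: |coefficient| beyond which a fit on standardized features is treated as
#: complete separation rather than a meaningful log-odds estimate.
_SEPARATION_BOUND = 15.0


@dataclass
class EndpointRules:
    """Composite time-to-insulin endpoint thresholds.

    Event = insulin treatment sustained for more than
    ``sustained_insulin_years`` (default six months), or a second HbA1c
    measurement above ``hba1c_threshold`` mmol/mol at least
    ``min_gap_years`` after an earlier qualifying one, both taken while on
    at least ``min_noninsulin_drugs`` non-insulin glucose-lowering drugs.
    """

    sustained_insulin_years: float = 0.5
    hba1c_threshold: float = 69.0
    min_gap_years: float = 0.25
    min_noninsulin_drugs: int = 2
    min_qualifying: int = 2

    def __post_init__(self) -> None:
        for name in ("sustained_insulin_years", "hba1c_threshold", "min_gap_years"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.min_noninsulin_drugs < 1 or self.min_qualifying < 2:
            raise ValueError("drug / qualifying-measurement counts too small")


@dataclass
class AssociationRow:
    feature_id: str
    coefficient: float
    std_error: float
    p_value: float
    q_value: float = np.nan
    converged: bool = True
    separation: bool = False


@dataclass
class CoxResult:
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n_events: int
    ties: str = "efron"
    converged: bool = True


def logistic_per_feature(
    block: OmicsBlock,
    labels,
    clinical: pd.DataFrame | None = None,
) -> list[AssociationRow]:
    """Marginal logistic regression of subgroup membership on each feature.

    Fits ``logit P(label = 2) ~ feature + age + sex + bmi`` separately per
    molecule by IRLS (covariates omitted when ``clinical`` is None).
    Features should arrive standardized so coefficients are log-odds per
    SD.  Complete separation (diverging |coefficient|) is flagged and its
    p-value set to NaN.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError(f"labels must be binary; saw groups {uniq}")
    y = (labels == uniq.max()).astype(float)

    covs = np.empty((len(y), 0))
    if clinical is not None:
        clin = clinical.set_index("patient_id").loc[block.patient_ids]
        covs = clin[["age", "sex", "bmi"]].to_numpy(dtype=float)

    rows: list[AssociationRow] = []
    X = block.values
    for j, feat in enumerate(block.feature_ids):
        design = sm.add_constant(np.column_stack([X[:, j], covs]), has_constant="add")
        converged, separation = True, False
        beta = se = p = np.nan
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.GLM(y, design, family=sm.families.Binomial()).fit(
                    maxiter=100, tol=1e-8
                )
            beta = float(fit.params[1])
            se = float(fit.bse[1])
            p = float(fit.pvalues[1])
            converged = bool(fit.converged)
        except Exception:
            converged = False
        if not np.isfinite(beta) or abs(beta) > _SEPARATION_BOUND or not converged:
            separation = abs(beta) > _SEPARATION_BOUND if np.isfinite(beta) else True
            p = np.nan
        rows.append(
            AssociationRow(
                feature_id=feat,
                coefficient=beta,
                std_error=se,
                p_value=p,
                converged=converged,
                separation=separation,
            )
        )
    qs = bh_adjust([r.p_value for r in rows])
    for r, q in zip(rows, qs):
        r.q_value = q
    return rows


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Missing entries are excluded from the correction and preserved as NaN;
    the mapping back to input positions is order-preserving.
    """
    p = np.asarray(p_values, dtype=float)
    q = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]  # step-up monotonicity
    ranked = np.minimum(ranked, 1.0)
    adj = np.empty(m)
    adj[order] = ranked
    q[mask] = adj
    return q


def _insulin_event_time(visits: pd.DataFrame, rules: EndpointRules) -> float | None:
    """Earliest insulin start sustained longer than the rule threshold."""
    flags = visits["insulin_flag"].to_numpy().astype(bool)
    times = visits["visit_time"].to_numpy()
    stops = visits.get("insulin_stop_time")
    stops = stops.to_numpy(dtype=float) if stops is not None else np.full(len(visits), np.nan)
    last_time = times[-1]
    i = 0
    n = len(visits)
    while i < n:
        if not flags[i]:
            i += 1
            continue
        start = times[i]
        j = i
        stop = np.nan
        while j < n and flags[j]:
            if not np.isnan(stops[j]):
                stop = stops[j]
            j += 1
        if not np.isnan(stop):
            end = stop
        elif j < n:
            # flag returned to 0 with no explicit stop: insulin was last
            # observed at the final flagged visit of the episode
            end = times[j - 1]
        else:
            end = last_time
        if end - start > rules.sustained_insulin_years:
            return float(start)
        i = j
    return None


def _hba1c_event_time(visits: pd.DataFrame, rules: EndpointRules) -> float | None:
    """Time of the final qualifying high-HbA1c measurement, if any."""
    qual = visits[
        (visits["hba1c"] > rules.hba1c_threshold)
        & (visits["n_noninsulin_drugs"] >= rules.min_noninsulin_drugs)
    ]["visit_time"].to_numpy()
    if qual.size < rules.min_qualifying:
        return None
    # earliest chain of min_qualifying measurements, consecutive ones
    # separated by at least min_gap_years
    chain = [qual[0]]
    for t in qual[1:]:
        if t - chain[-1] >= rules.min_gap_years:
            chain.append(t)
        if len(chain) >= rules.min_qualifying:
            return float(chain[-1])
    return None


def derive_time_to_insulin(
    records: pd.DataFrame, rules: EndpointRules | None = None
) -> pd.DataFrame:
    """Derive the composite (time, event) endpoint per patient.

    The event time is the earliest of the sustained-insulin rule and the
    repeated-high-HbA1c rule; patients qualifying under neither are
    censored at their last visit.  Duplicated visit rows are ignored.
    """
    rules = rules or EndpointRules()
    req = {"patient_id", "visit_time", "hba1c", "n_noninsulin_drugs", "insulin_flag"}
    missing = req - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    if records.empty:
        raise ValueError("no visit records supplied")
    out = []
    for pid, visits in records.groupby("patient_id", sort=True):
        visits = (
            visits.drop_duplicates()
            .sort_values("visit_time", kind="stable")
            .reset_index(drop=True)
        )
        if visits.empty:
            raise ValueError(f"patient {pid} has no visits")
        candidates = [
            t
            for t in (
                _insulin_event_time(visits, rules),
                _hba1c_event_time(visits, rules),
            )
            if t is not None
        ]
        if candidates:
            out.append({"patient_id": pid, "time": min(candidates), "event": 1})
        else:
            out.append(
                {
                    "patient_id": pid,
                    "time": float(visits["visit_time"].iloc[-1]),
                    "event": 0,
                }
            )
    return pd.DataFrame(out)


def cox_ph(
    time,
    event,
    group,
    clinical: pd.DataFrame | None = None,
    ties: str = "efron",
) -> CoxResult:
    """Cox proportional hazards for subgroup membership.

    ``group`` is binary (coded internally as an indicator for its larger
    level, so the hazard ratio compares the second subgroup against the
    first); age, sex and BMI enter as covariates when ``clinical`` is
    given.  Efron tie handling is the default; Breslow is available via
    ``ties="breslow"``.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    uniq = np.unique(group)
    if uniq.size != 2:
        raise ValueError("group must be binary")
    if event.sum() == 0:
        raise ValueError("no events observed")
    g = (group == uniq.max()).astype(float)
    if event[g == 1].sum() == 0 or event[g == 0].sum() == 0:
        # monotone partial likelihood: HR estimate escapes to 0 or infinity
        return CoxResult(
            hazard_ratio=np.nan,
            ci_low=np.nan,
            ci_high=np.nan,
            p_value=np.nan,
            n_events=int(event.sum()),
            ties=ties,
            converged=False,
        )

    df = pd.DataFrame({"time": time, "event": event, "group": g})
    if clinical is not None:
        for col in ("age", "sex", "bmi"):
            df[col] = clinical[col].to_numpy(dtype=float)

    if ties == "efron":
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time", event_col="event")
        beta = float(cph.params_["group"])
        se = float(cph.standard_errors_["group"])
        p = float(cph.summary.loc["group", "p"])
    elif ties == "breslow":
        covs = df.drop(columns=["time", "event"])
        fit = sm.PHReg(
            df["time"], covs, status=df["event"], ties="breslow"
        ).fit()
        idx = list(covs.columns).index("group")
        beta = float(fit.params[idx])
        se = float(fit.bse[idx])
        p = float(fit.pvalues[idx])
    else:
        raise ValueError("ties must be 'efron' or 'breslow'")

    z = 1.959963984540054
    return CoxResult(
        hazard_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - z * se)),
        ci_high=float(np.exp(beta + z * se)),
        p_value=p,
        n_events=int(event.sum()),
        ties=ties,
    )


def overlap_enrichment(labels_a, labels_b) -> pd.DataFrame:
    """Hypergeometric over-representation of every cluster-pair overlap.

    For clusters a and b over the same N patients, the one-sided p-value is
    ``P(X >= |a & b|)`` for X ~ Hypergeometric(N, |a|, |b|).
    """
    a = pd.Series(labels_a)
    b = pd.Series(labels_b)
    if len(a) != len(b):
        raise ValueError("labelings must cover the same patients")
    N = len(a)
    rows = []
    for ca in sorted(a.unique()):
        for cb in sorted(b.unique()):
            na = int((a == ca).sum())
            nb = int((b == cb).sum())
            inter = int(((a == ca) & (b == cb)).sum())
            p = float(hypergeom.sf(inter - 1, N, na, nb))
            rows.append(
                {
                    "cluster_a": ca,
                    "cluster_b": cb,
                    "size_a": na,
                    "size_b": nb,
                    "intersect": inter,
                    "p_value": min(p, 1.0),
                }
            )
    return pd.DataFrame(rows)
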