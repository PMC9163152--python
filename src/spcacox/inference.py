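"""Interpretability layer: from significant components back to exposures.

Once a Cox model on component scores flags a component, the sparse weight
matrix makes the finding actionable: the component's support names the few
exposures involved, a one-unit score change converts to raw-unit changes of
those exposures, and the hazard ratio can be restated per a convenient raw
increment (e.g. per 10 dB of noise).  Dense-PCA components, whose support
is every variable, are refused above a configurable interpretability cap —
that refusal is the PCA failure mode the sparse variant exists to fix.

A decile exposure-response stage probes dose-response: a composite exposure
(the unweighted mean of same-unit variables) is cut into sample deciles,
hazard ratios of deciles 2-10 are estimated against the lowest decile, and
the remaining exposures are collapsed to dense principal components (92%
variance by default) to keep the adjustment free of multicollinearity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_selection import select_n_components
from .preprocessing import StandardizedMatrix, standardize
from .sparse_pca import PCA, SparsePCA
from .survival import CoxPH


class NonIdentifiableComponentError(ValueError):
    """A significant component loads on too many variables to attribute."""


@dataclass
class AttributionEntry:
    component: str
    coef: float
    se: float
    p: float
    hr: float
    ci_low: float
    ci_high: float
    variables: list[str]
    weights: list[float]
    raw_unit_changes: list[float] | None = None
    mean_raw_change: float | None = None
    unit: str | None = None


@dataclass
class AttributionReport:
    alpha: float
    entries: list[AttributionEntry] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            for v, w, rc in zip(
                e.variables, e.weights,
                e.raw_unit_changes if e.raw_unit_changes is not None else [np.nan] * len(e.variables),
            ):
                rows.append({
                    "component": e.component, "coef": e.coef, "se": e.se, "p": e.p,
                    "HR": e.hr, "ci_low": e.ci_low, "ci_high": e.ci_high,
                    "variable": v, "weight": w, "raw_unit_change": rc,
                    "mean_raw_change": e.mean_raw_change, "unit": e.unit,
                })
        cols = ["component", "coef", "se", "p", "HR", "ci_low", "ci_high",
                "variable", "weight", "raw_unit_change", "mean_raw_change", "unit"]
        return pd.DataFrame(rows, columns=cols)


def pc_unit_in_raw_units(weights, sds, units=None) -> tuple[np.ndarray, float | None]:
    """Raw-unit change of each support variable per one-unit score increase.

    A unit increase of the score z = b'x along the loading direction moves
    standardized variable i by b_i/||b||^2, i.e. s_i * b_i/||b||^2 raw units.
    The aggregate (mean over the support) is reported only when all support
    variables share a physical unit.
    """
    b = np.asarray(weights, dtype=float)
    s = np.asarray(sds, dtype=float)
    if b.size == 0 or not np.any(b != 0):
        raise ValueError("support is empty")
    raw = s * b / float(b @ b)
    mean_change: float | None = float(np.mean(raw))
    if units is not None:
        uniq = set(units)
        if len(uniq) > 1:
            mean_change = None
    return raw, mean_change


def rescale_hr(hr: float, ci: tuple[float, float], per: float, target: float) -> tuple[float, tuple[float, float]]:
    """Restate an HR quoted per ``per`` raw units as per ``target`` raw units
    (logs scale linearly: each bound is raised to the power target/per)."""
    low, high = ci
    if min(hr, low, high, per, target) <= 0:
        raise ValueError("hr, ci bounds, per and target must all be positive")
    k = target / per
    return hr ** k, (low ** k, high ** k)


def make_composite(columns) -> pd.Series | np.ndarray:
    """Row-wise unweighted mean of same-unit exposure columns (raw units)."""
    if isinstance(columns, pd.DataFrame):
        if columns.shape[1] < 1:
            raise ValueError("need at least one column")
        return columns.mean(axis=1)
    arrays = [np.asarray(c, dtype=float) for c in columns]
    if len(arrays) < 1:
        raise ValueError("need at least one column")
    lengths = {a.shape[0] for a in arrays}
    if len(lengths) != 1:
        raise ValueError(f"column lengths differ: {sorted(lengths)}")
    return np.mean(arrays, axis=0)


def trace_attribution(
    fit: SparsePCA,
    cox: CoxPH,
    alpha: float = 0.05,
    variable_names=None,
    component_terms=None,
    sds=None,
    units=None,
    max_support: int = 6,
) -> AttributionReport:
    """Map each component significant at ``alpha`` to its support variables.

    Raises :class:`NonIdentifiableComponentError` when a significant
    component's support exceeds ``max_support`` variables — there is then no
    defensible way to assign the association to individual exposures.
    """
    k = fit.weights_.shape[1]
    p = fit.weights_.shape[0]
    names = list(variable_names) if variable_names is not None else [f"v{i}" for i in range(p)]
    terms = list(component_terms) if component_terms is not None else [f"PC{j + 1}" for j in range(k)]
    summary = cox.summary_
    missing = [t for t in terms if t not in summary.index]
    if missing:
        raise ValueError(f"Cox result lacks component terms {missing}")
    report = AttributionReport(alpha=alpha)
    supports = fit.support()
    for j, term in enumerate(terms):
        row = summary.loc[term]
        if not row["p"] < alpha:
            continue
        sup = supports[j]
        if sup.size > max_support:
            raise NonIdentifiableComponentError(
                f"component {term} is significant (p={row['p']:.3g}) but loads on "
                f"{sup.size} variables (cap {max_support}); the association cannot "
                f"be disentangled into individual exposures"
            )
        if sup.size == 0:
            continue
        weights = fit.weights_[sup, j]
        entry = AttributionEntry(
            component=term,
            coef=float(row["coef"]), se=float(row["se"]), p=float(row["p"]),
            hr=float(row["HR"]), ci_low=float(row["ci_low"]), ci_high=float(row["ci_high"]),
            variables=[names[i] for i in sup],
            weights=[float(w) for w in weights],
        )
        if sds is not None:
            s = np.asarray(sds, dtype=float)[sup]
            u = [units[names[i]] for i in sup] if units else None
            raw, mean_change = pc_unit_in_raw_units(weights, s, units=u)
            entry.raw_unit_changes = [float(r) for r in raw]
            entry.mean_raw_change = mean_change
            if u and len(set(u)) == 1:
                entry.unit = u[0]
        report.entries.append(entry)
    return report


def link_diagram_edges(
    fit: SparsePCA,
    cox: CoxPH,
    variable_names=None,
    component_terms=None,
    support_tol: float = 1e-8,
) -> pd.DataFrame:
    """Generic nodes/edges table (source, target, weight) for Sankey-style
    rendering: variable -> component edges weighted by loadings, and
    component -> outcome edges weighted by |log HR|."""
    p, k = fit.weights_.shape
    names = list(variable_names) if variable_names is not None else [f"v{i}" for i in range(p)]
    terms = list(component_terms) if component_terms is not None else [f"PC{j + 1}" for j in range(k)]
    summary = cox.summary_
    rows = []
    for j, term in enumerate(terms):
        for i in np.flatnonzero(np.abs(fit.weights_[:, j]) > support_tol):
            rows.append({"source": names[i], "target": term,
                         "weight": float(fit.weights_[i, j])})
        if term in summary.index:
            rows.append({"source": term, "target": "outcome",
                         "weight": float(abs(summary.loc[term, "coef"]))})
    return pd.DataFrame(rows, columns=["source", "target", "weight"])


# ---------------------------------------------------------------------------
# decile exposure-response

@dataclass
class DecileResult:
    boundaries: list[tuple[float, float]]  # 10 half-open intervals (a, b]
    counts: np.ndarray                     # subjects per decile
    table: pd.DataFrame                    # deciles 2..10: coef, se, p, HR, CI
    model: CoxPH
    n_adjustment_pcs: int

    def as_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out.insert(0, "interval", [
            f"({a:.6g}, {b:.6g}]" for a, b in self.boundaries[1:]
        ])
        out.insert(1, "n_subjects", self.counts[1:])
        return out


def assign_deciles(values: np.ndarray) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Sample-decile assignment with half-open intervals (a, b]; ties go to
    the lower decile.  Returns (decile index 0..9 per subject, boundaries)."""
    x = np.asarray(values, dtype=float)
    if np.unique(x).size < 10:
        raise ValueError("composite has fewer than 10 distinct values")
    qs = np.quantile(x, np.arange(1, 10) / 10.0)
    idx = np.searchsorted(qs, x, side="left")  # x <= q goes to the lower decile
    edges = [float(x.min())] + [float(q) for q in qs] + [float(x.max())]
    boundaries = [(edges[i], edges[i + 1]) for i in range(10)]
    return idx, boundaries


def decile_exposure_response(
    composite,
    other_exposures,
    covariates,
    time,
    event,
    pca_threshold: float = 0.92,
    alpha: float = 0.05,
) -> DecileResult:
    """Cox model of decile indicators (lowest decile = reference) adjusted
    for dense principal components of the remaining exposures plus the
    other covariates."""
    comp = np.asarray(composite, dtype=float)
    if np.var(comp) == 0:
        raise ValueError("composite has zero variance")
    idx, boundaries = assign_deciles(comp)
    counts = np.bincount(idx, minlength=10)
    indicators = pd.DataFrame(
        {f"decile_{d + 1}": (idx == d).astype(float) for d in range(1, 10)}
    )

    if isinstance(other_exposures, StandardizedMatrix):
        Z = other_exposures
    else:
        Z = standardize(pd.DataFrame(other_exposures))
    pca = PCA(n_components=Z.frame.shape[1]).fit(Z.frame.to_numpy())
    k = select_n_components(pca.explained_variance_ratio_, pca_threshold)
    scores = pca.transform(Z.frame.to_numpy())[:, :k]
    pcs = pd.DataFrame(scores, columns=[f"adjPC{j + 1}" for j in range(k)])

    cov = pd.DataFrame(covariates).reset_index(drop=True)
    design = pd.concat(
        [indicators.reset_index(drop=True), pcs.reset_index(drop=True), cov], axis=1
    )
    model = CoxPH(alpha=alpha).fit(design, (np.asarray(time, float), np.asarray(event)))
    table = model.summary_.loc[[f"decile_{d}" for d in range(2, 11)]]
    return DecileResult(
        boundaries=boundaries,
        counts=counts,
        table=table,
        model=model,
        n_adjustment_pcs=k,
    )
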