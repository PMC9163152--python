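"""End-to-end orchestration: exclusions, the four-way model comparison,
and the decile exposure-response stage.

The comparison fits, on one shared standardized design:

(a) a raw Cox model on all exposures and covariates;
(b) an L1-penalized Cox path over the configured lambda grid (exposures
    penalized, covariates not);
(c) a PCA-Cox model, components chosen to reach the variance threshold;
(d) an SPCA-Cox model with the disjoint-support penalty, followed by
    attribution of significant components back to exposures.

Stage failures are recorded per block and do not abort the other blocks.
Given a config and a seed, every output table is reproducible byte for
byte.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from .config import config_hash, default_config
from .inference import (
    DecileResult,
    NonIdentifiableComponentError,
    decile_exposure_response,
    link_diagram_edges,
    make_composite,
    trace_attribution,
)
from .model_selection import (
    default_lambda_grid,
    select_lambda_disjoint,
    select_n_components,
)
from .preprocessing import correlation_matrix, standardize, winsorize
from .sparse_pca import PCA, SparsePCA
from .survival import CoxL1Path, CoxPH

_FLOAT_FMT = "%.10g"


# ---------------------------------------------------------------------------
# exclusion accounting

@dataclass
class ExclusionAudit:
    starting_count: int
    steps: list[tuple[str, int]]

    def __post_init__(self) -> None:
        if any(r < 0 for _, r in self.steps):
            raise ValueError("removal counts must be nonnegative")

    @property
    def final_count(self) -> int:
        return self.starting_count - sum(r for _, r in self.steps)

    def as_frame(self) -> pd.DataFrame:
        rows = [{"filter": "starting_count", "removed": 0, "remaining": self.starting_count}]
        remaining = self.starting_count
        for name, removed in self.steps:
            remaining -= removed
            rows.append({"filter": name, "removed": removed, "remaining": remaining})
        return pd.DataFrame(rows)


def audit_from_counts(starting_count: int, steps) -> ExclusionAudit:
    """Audit from pre-tabulated (filter name, removed count) pairs."""
    return ExclusionAudit(starting_count=int(starting_count), steps=[(str(n), int(r)) for n, r in steps])


def apply_exclusions(table: pd.DataFrame, filters) -> tuple[pd.DataFrame, ExclusionAudit]:
    """Apply ordered (name, predicate) filters; a predicate returns a boolean
    mask of subjects to REMOVE.  Each subject is charged to the first filter
    that catches it."""
    start = len(table)
    steps: list[tuple[str, int]] = []
    current = table
    for name, predicate in filters:
        mask = np.asarray(predicate(current), dtype=bool)
        steps.append((str(name), int(mask.sum())))
        current = current.loc[~mask]
    return current.reset_index(drop=True), ExclusionAudit(starting_count=start, steps=steps)


# ---------------------------------------------------------------------------
# comparison report

@dataclass
class ModelBlock:
    name: str
    table: pd.DataFrame | None = None
    metadata: dict = field(default_factory=dict)
    loadings: pd.DataFrame | None = None  # variables x components, when applicable
    error: str | None = None


@dataclass
class ComparisonReport:
    raw_cox: ModelBlock
    penalized_cox: ModelBlock
    pca_cox: ModelBlock
    spca_cox: ModelBlock
    attribution: pd.DataFrame | None
    attribution_note: str | None
    correlation: pd.DataFrame
    selection: dict
    config_hash: str
    seed: int | None
    selection_report: pd.DataFrame | None = None  # per-lambda support/overlap audit
    link_edges: pd.DataFrame | None = None        # nodes/edges table for Sankey-style plots

    def blocks(self) -> list[ModelBlock]:
        return [self.raw_cox, self.penalized_cox, self.pca_cox, self.spca_cox]

    def run_summary(self) -> str:
        buf = io.StringIO()
        print(f"config_hash: {self.config_hash}", file=buf)
        print(f"seed: {self.seed}", file=buf)
        for key, val in sorted(self.selection.items()):
            print(f"{key}: {val}", file=buf)
        for block in self.blocks():
            status = "error: " + block.error if block.error else "ok"
            print(f"block {block.name}: {status}", file=buf)
            for key, val in sorted(block.metadata.items()):
                print(f"  {key}: {val}", file=buf)
        if self.attribution_note:
            print(f"attribution: {self.attribution_note}", file=buf)
        return buf.getvalue()

    def to_dir(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for block in self.blocks():
            if block.table is not None:
                block.table.to_csv(out / f"{block.name}.tsv", sep="\t", float_format=_FLOAT_FMT)
            if block.loadings is not None:
                block.loadings.to_csv(out / f"{block.name}_loadings.tsv", sep="\t", float_format=_FLOAT_FMT)
        if self.attribution is not None:
            self.attribution.to_csv(out / "attribution.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
        if self.selection_report is not None:
            self.selection_report.to_csv(out / "lambda_selection.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
        if self.link_edges is not None:
            self.link_edges.to_csv(out / "link_edges.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
        self.correlation.to_csv(out / "correlation.tsv", sep="\t", float_format=_FLOAT_FMT)
        (out / "run_summary.txt").write_text(self.run_summary(), encoding="utf-8")


def _resolve_columns(table: pd.DataFrame, cfg: dict) -> tuple[list[str], list[str], str, str]:
    cols = cfg["columns"]
    covs = [c for c in cols["covariates"] if c in table.columns]
    exposures = cols["exposures"]
    if exposures is None:
        drop = set(covs) | {cols["time"], cols["event"], cols.get("id", "subject_id")}
        exposures = [c for c in table.columns if c not in drop]
    return list(exposures), covs, cols["time"], cols["event"]


def _exposure_units(exposures: list[str]) -> dict[str, str | None]:
    units: dict[str, str | None] = {}
    for name, unit, _r, cols in cohort_mod._EXPOSURE_BLOCKS:
        for v, _m, _s in cols:
            units[v] = unit
    return {e: units.get(e) for e in exposures}


def run_comparison(table: pd.DataFrame, config: dict | None = None, seed: int | None = None) -> ComparisonReport:
    cfg = config or default_config()
    exposures, covs, time_col, event_col = _resolve_columns(table, cfg)
    time = table[time_col].to_numpy(dtype=float)
    event = table[event_col].to_numpy()
    bound = cfg["preprocessing"]["winsor_bound"]
    alpha = cfg["cox"]["alpha"]

    # one standardized matrix shared by every stage
    sm_exp = winsorize(standardize(table[exposures], units=_exposure_units(exposures)), bound)
    sm_cov = winsorize(standardize(table[covs]), bound) if covs else None
    X_exp = sm_exp.frame
    design_raw = pd.concat([X_exp, sm_cov.frame], axis=1) if sm_cov is not None else X_exp
    corr = correlation_matrix(design_raw)

    selection: dict = {}

    raw_block = ModelBlock("raw_cox")
    try:
        fit = CoxPH(alpha=alpha).fit(design_raw, (time, event))
        raw_block.table = fit.summary_
        raw_block.metadata = {"converged": fit.converged_, "log_likelihood": fit.log_likelihood_}
    except Exception as exc:  # noqa: BLE001 - stage failures are recorded
        raw_block.error = repr(exc)

    pen_block = ModelBlock("penalized_cox")
    try:
        g = cfg["cox"]["lambda_grid"]
        lambdas = np.arange(0.0, g["stop"] + g["step"] / 2, g["step"]) + g["start"]
        mask = np.array([c in exposures for c in design_raw.columns])
        path = CoxL1Path(lambdas=lambdas, penalized=mask).fit(design_raw, (time, event))
        pen_block.table = path.path_frame_.set_index("lambda")
        pen_block.metadata = {
            "n_lambdas": len(lambdas),
            "n_converged": int(path.converged_.sum()),
            "penalty_scale": path.penalty_scale_,
        }
    except Exception as exc:  # noqa: BLE001
        pen_block.error = repr(exc)

    pca_block = ModelBlock("pca_cox")
    attribution = None
    attribution_note = None
    pca_scores = None
    k = None
    try:
        pca_full = PCA(n_components=X_exp.shape[1]).fit(X_exp.to_numpy())
        k = select_n_components(pca_full.explained_variance_ratio_, cfg["pca"]["variance_threshold"])
        selection["pca_n_components"] = k
        pca_scores = pca_full.transform(X_exp.to_numpy())[:, :k]
        pc_names = [f"PC{j + 1}" for j in range(k)]
        design = pd.concat(
            [pd.DataFrame(pca_scores, columns=pc_names), sm_cov.frame.reset_index(drop=True)], axis=1
        ) if sm_cov is not None else pd.DataFrame(pca_scores, columns=pc_names)
        fit = CoxPH(alpha=alpha).fit(design, (time, event))
        pca_block.table = fit.summary_
        pca_block.metadata = {"n_components": k, "converged": fit.converged_}
        pca_block.loadings = pd.DataFrame(
            pca_full.components_[:k].T, index=X_exp.columns, columns=pc_names
        )
        # attribution of dense components is expected to be refused
        try:
            dense = SparsePCA(n_components=k, alpha=0.0).fit(X_exp.to_numpy())
            trace_attribution(
                dense, fit, alpha=cfg["attribution"]["alpha"],
                variable_names=list(X_exp.columns), component_terms=pc_names,
                max_support=cfg["attribution"]["max_support"],
            )
        except NonIdentifiableComponentError as exc:
            pca_block.metadata["attribution_refusal"] = str(exc)
    except Exception as exc:  # noqa: BLE001
        pca_block.error = repr(exc)

    spca_block = ModelBlock("spca_cox")
    selection_report = None
    link_edges = None
    try:
        spca_cfg = cfg["spca"]
        grid_cfg = spca_cfg["lambda_grid"]
        grid = default_lambda_grid(num=grid_cfg["num"], low=grid_cfg["low"], high=grid_cfg["high"])
        if spca_cfg.get("order", "k_then_lambda") == "k_then_lambda":
            if k is None:
                dense = SparsePCA(n_components=X_exp.shape[1], alpha=0.0).fit(X_exp.to_numpy())
                k = select_n_components(dense.explained_variance_ratio_, cfg["pca"]["variance_threshold"])
            sel = select_lambda_disjoint(
                X_exp.to_numpy(), k, grid=grid, penalty=spca_cfg["penalty"],
                l1_ratio=spca_cfg["l1_ratio"], support_tol=spca_cfg["support_tol"],
            )
        else:  # lambda_then_k: disjointness at full rank, then trim by variance
            sel = select_lambda_disjoint(
                X_exp.to_numpy(), X_exp.shape[1], grid=grid, penalty=spca_cfg["penalty"],
                l1_ratio=spca_cfg["l1_ratio"], support_tol=spca_cfg["support_tol"],
            )
            k = select_n_components(sel.fit.explained_variance_ratio_, cfg["pca"]["variance_threshold"])
        selection["spca_lambda_star"] = sel.lambda_star
        selection["spca_n_components"] = k
        selection_report = sel.report
        spca_fit = sel.fit
        scores = spca_fit.transform(X_exp.to_numpy())[:, :k]
        sc_names = [f"SPC{j + 1}" for j in range(k)]
        design = pd.concat(
            [pd.DataFrame(scores, columns=sc_names), sm_cov.frame.reset_index(drop=True)], axis=1
        ) if sm_cov is not None else pd.DataFrame(scores, columns=sc_names)
        fit = CoxPH(alpha=alpha).fit(design, (time, event))
        spca_block.table = fit.summary_
        spca_block.loadings = pd.concat(
            [
                pd.DataFrame(spca_fit.weights_[:, :k], index=X_exp.columns, columns=sc_names),
                pd.DataFrame(
                    spca_fit.ortho_[:, :k], index=X_exp.columns,
                    columns=[f"{c}_ortho" for c in sc_names],
                ),
            ],
            axis=1,
        )
        supports = spca_fit.support()
        spca_block.metadata = {
            "n_components": k,
            "lambda_star": sel.lambda_star,
            "converged": fit.converged_,
            "supports": "; ".join(
                f"SPC{j + 1}=" + ",".join(X_exp.columns[i] for i in supports[j]) for j in range(k)
            ),
        }
        link_edges = link_diagram_edges(
            spca_fit, fit, variable_names=list(X_exp.columns), component_terms=sc_names
        )
        try:
            attribution = trace_attribution(
                spca_fit, fit, alpha=cfg["attribution"]["alpha"],
                variable_names=list(X_exp.columns), component_terms=sc_names,
                sds=sm_exp.sds[list(X_exp.columns)].to_numpy(),
                units=sm_exp.units,
                max_support=cfg["attribution"]["max_support"],
            ).as_frame()
            attribution_note = f"{len(attribution['component'].unique()) if len(attribution) else 0} significant component(s)"
        except NonIdentifiableComponentError as exc:
            attribution_note = f"refused: {exc}"
    except Exception as exc:  # noqa: BLE001
        spca_block.error = repr(exc)

    return ComparisonReport(
        raw_cox=raw_block,
        penalized_cox=pen_block,
        pca_cox=pca_block,
        spca_cox=spca_block,
        attribution=attribution,
        attribution_note=attribution_note,
        correlation=corr,
        selection=selection,
        config_hash=config_hash(cfg),
        seed=seed,
        selection_report=selection_report,
        link_edges=link_edges,
    )


def run_decile_stage(table: pd.DataFrame, config: dict | None = None, seed: int | None = None) -> DecileResult:
    cfg = config or default_config()
    exposures, covs, time_col, event_col = _resolve_columns(table, cfg)
    composite_cols = cfg["decile"]["composite_columns"]
    missing = [c for c in composite_cols if c not in table.columns]
    if missing:
        raise ValueError(f"composite columns missing from table: {missing}")
    composite = make_composite(table[composite_cols])
    others = [c for c in exposures if c not in composite_cols]
    bound = cfg["preprocessing"]["winsor_bound"]
    sm_other = winsorize(standardize(table[others]), bound)
    sm_cov = winsorize(standardize(table[covs]), bound) if covs else pd.DataFrame(index=table.index)
    cov_frame = sm_cov.frame if hasattr(sm_cov, "frame") else sm_cov
    return decile_exposure_response(
        composite,
        sm_other,
        cov_frame,
        table[time_col].to_numpy(dtype=float),
        table[event_col].to_numpy(),
        pca_threshold=cfg["decile"]["variance_threshold"],
        alpha=cfg["cox"]["alpha"],
    )
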