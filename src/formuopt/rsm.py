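"""Full quadratic response-surface modelling: least-squares fitting, ANOVA
with lack-of-fit decomposition, main-effect screening for Plackett-Burman
data, and prediction.

The model is the 10-term full quadratic in three factors:

    y = b0 + b1*x1 + b2*x2 + b3*x3
        + b12*x1*x2 + b13*x1*x3 + b23*x2*x3
        + b11*x1^2 + b22*x2^2 + b33*x3^2

optionally augmented with a fixed block effect (sum-to-zero contrast) for
two-block designs.  Term sums of squares are partial (Type-III), computed
by extra-sum-of-squares against the full model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignMatrix, ResponseTable

__all__ = [
    "QuadraticModel",
    "AnovaTable",
    "EffectEstimate",
    "fit_quadratic",
    "anova",
    "screen_effects",
    "quadratic_design_matrix",
]

TERM_NAMES = ["X1", "X2", "X3", "X1X2", "X1X3", "X2X3", "X1^2", "X2^2", "X3^2"]


def quadratic_design_matrix(X: np.ndarray) -> np.ndarray:
    """Model matrix [1, x1, x2, x3, x1x2, x1x3, x2x3, x1^2, x2^2, x3^2]."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError(f"expected an n x 3 array, got shape {X.shape}")
    x1, x2, x3 = X[:, 0], X[:, 1], X[:, 2]
    return np.column_stack(
        [np.ones(len(X)), x1, x2, x3, x1 * x2, x1 * x3, x2 * x3, x1**2, x2**2, x3**2]
    )


@dataclass
class QuadraticModel:
    """The 10-coefficient full quadratic surface in three factors."""

    factor_names: tuple[str, str, str]
    intercept: float
    linear: tuple[float, float, float]
    interaction: tuple[float, float, float]  # (x1x2, x1x3, x2x3)
    quadratic: tuple[float, float, float]
    scale: str = "actual"  # "actual" or "coded"
    block_effects: dict[int, float] | None = None

    @property
    def coefficients(self) -> np.ndarray:
        """All 10 coefficients in model-matrix column order."""
        return np.array(
            [self.intercept, *self.linear, *self.interaction, *self.quadratic], dtype=float
        )

    @classmethod
    def from_coefficients(
        cls,
        beta: np.ndarray,
        factor_names: tuple[str, str, str] = ("X1", "X2", "X3"),
        scale: str = "actual",
        block_effects: dict[int, float] | None = None,
    ) -> "QuadraticModel":
        beta = np.asarray(beta, dtype=float)
        if beta.shape != (10,):
            raise ValueError(f"expected 10 coefficients, got shape {beta.shape}")
        return cls(
            factor_names=tuple(factor_names),
            intercept=float(beta[0]),
            linear=tuple(beta[1:4]),
            interaction=tuple(beta[4:7]),
            quadratic=tuple(beta[7:10]),
            scale=scale,
            block_effects=block_effects,
        )

    def predict(self, x) -> float | np.ndarray:
        """Evaluate the surface at a 3-vector or an n x 3 array of settings."""
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        if single:
            if x.shape != (3,):
                raise ValueError(f"expected a 3-vector, got shape {x.shape}")
            x = x[None, :]
        out = quadratic_design_matrix(x) @ self.coefficients
        return float(out[0]) if single else out


def _solve_ls(M: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Least squares with a rank check; returns (beta, residual SS)."""
    beta, _, rank, _ = np.linalg.lstsq(M, y, rcond=None)
    if rank < M.shape[1]:
        raise np.linalg.LinAlgError(
            f"singular design: model matrix rank {rank} < {M.shape[1]} columns"
        )
    resid = y - M @ beta
    return beta, float(resid @ resid)


def _model_columns(
    design: DesignMatrix, scale: str, block_handling: str
) -> tuple[np.ndarray, np.ndarray | None]:
    if scale == "actual":
        X = design.actual_array()
    elif scale == "coded":
        X = design.coded_array()
    else:
        raise ValueError(f"scale must be 'actual' or 'coded', got {scale!r}")
    M = quadratic_design_matrix(X)
    blocks = np.array([p.block for p in design.points])
    block_col = None
    if block_handling == "fixed_effect" and len(np.unique(blocks)) == 2:
        # sum-to-zero contrast: +1 in block 1, -1 in block 2
        block_col = np.where(blocks == 1, 1.0, -1.0)
    elif block_handling not in ("fixed_effect", "ignore"):
        raise ValueError(f"block_handling must be 'ignore' or 'fixed_effect', got {block_handling!r}")
    return M, block_col


def fit_quadratic(
    design: DesignMatrix,
    responses: ResponseTable,
    response_name: str,
    scale: str = "actual",
    block_handling: str = "fixed_effect",
) -> QuadraticModel:
    """Least-squares fit of the full quadratic to a design and its responses.

    With ``block_handling='fixed_effect'`` (default) a sum-to-zero block
    contrast is estimated alongside the 10 surface coefficients, so the
    surface predicts at the block average.
    """
    y = responses.aligned_values(design, response_name)
    M, block_col = _model_columns(design, scale, block_handling)
    if len(y) < M.shape[1] + (1 if block_col is not None else 0) + 1:
        raise ValueError("not enough runs to fit the full quadratic with residual df")
    full = M if block_col is None else np.column_stack([M, block_col])
    beta, _ = _solve_ls(full, y)
    block_effects = None
    if block_col is not None:
        b = float(beta[-1])
        block_effects = {1: b, 2: -b}
    names = tuple(design.factor_names[:3])
    return QuadraticModel.from_coefficients(
        beta[:10], factor_names=names, scale=scale, block_effects=block_effects
    )


@dataclass
class AnovaTable:
    """Per-term partial sums of squares plus lack-of-fit decomposition.

    ``rows`` is indexed by term name (Model, X1, ..., X3^2, Block, Residual,
    Lack of Fit, Pure Error, Cor Total) with columns sum_sq, df, f_value,
    p_value (NaN where undefined).
    """

    rows: pd.DataFrame
    r_squared: float

    def sum_sq(self, term: str) -> float:
        return float(self.rows.loc[term, "sum_sq"])

    def df(self, term: str) -> int:
        return int(self.rows.loc[term, "df"])

    def check_consistency(self, rtol: float = 1e-9) -> None:
        """Verify SS(LOF) + SS(PE) = SS(Residual) and the SS decomposition."""
        resid = self.sum_sq("Residual")
        if "Lack of Fit" in self.rows.index:
            lof_pe = self.sum_sq("Lack of Fit") + self.sum_sq("Pure Error")
            if not np.isclose(lof_pe, resid, rtol=rtol, atol=1e-12):
                raise AssertionError(f"LOF+PE={lof_pe} != Residual={resid}")
        parts = self.sum_sq("Model") + resid
        if "Block" in self.rows.index:
            parts += self.sum_sq("Block")
        total = self.sum_sq("Cor Total")
        if not np.isclose(parts, total, rtol=rtol, atol=1e-9):
            raise AssertionError(f"Model(+Block)+Residual={parts} != Cor Total={total}")


def anova(
    design: DesignMatrix,
    responses: ResponseTable,
    model: QuadraticModel,
    response_name: str | None = None,
) -> AnovaTable:
    """ANOVA for a fitted quadratic model with partial (Type-III) term SS.

    Pure error is pooled over replicate groups (identical factor settings)
    within each block; lack of fit is the remainder of the residual.  R^2 is
    1 - SS(Residual)/SS(Cor Total), with the corrected total taken about the
    grand mean (block SS, when fitted, is shown as its own row).
    """
    if response_name is None:
        # single-response tables can omit the name
        cols = list(responses.frame.columns)
        if len(cols) != 1:
            raise ValueError("response_name required when the table has several responses")
        response_name = cols[0]
    y = responses.aligned_values(design, response_name)
    n = len(y)
    block_handling = "fixed_effect" if model.block_effects is not None else "ignore"
    M, block_col = _model_columns(design, model.scale, block_handling)
    full = M if block_col is None else np.column_stack([M, block_col])
    _, sse = _solve_ls(full, y)
    df_resid = n - full.shape[1]
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom: F-statistics undefined")
    mse = sse / df_resid

    ss_total = float(np.sum((y - y.mean()) ** 2))

    # sequential blocks-first decomposition so that
    # SS(Block) + SS(Model) + SS(Residual) == SS(Cor Total) exactly
    records: list[dict] = []
    ss_block = 0.0
    base_cols = [0] if block_col is None else [0, full.shape[1] - 1]
    _, sse_base = _solve_ls(full[:, base_cols], y)
    if block_col is not None:
        ss_block = ss_total - sse_base  # extra SS of block over the grand mean
    # model SS: joint extra SS of the 9 surface terms over intercept (+ block)
    ss_model = sse_base - sse
    f_model = (ss_model / 9) / mse
    records.append(
        {
            "term": "Model",
            "sum_sq": ss_model,
            "df": 9,
            "f_value": f_model,
            "p_value": stats.f.sf(f_model, 9, df_resid),
        }
    )

    for j, term in enumerate(TERM_NAMES, start=1):
        keep = [c for c in range(full.shape[1]) if c != j]
        _, sse_drop = _solve_ls(full[:, keep], y)
        ss_term = max(sse_drop - sse, 0.0)
        f_term = ss_term / mse
        records.append(
            {
                "term": term,
                "sum_sq": ss_term,
                "df": 1,
                "f_value": f_term,
                "p_value": stats.f.sf(f_term, 1, df_resid),
            }
        )

    if block_col is not None:
        records.append(
            {"term": "Block", "sum_sq": ss_block, "df": 1, "f_value": np.nan, "p_value": np.nan}
        )

    records.append(
        {"term": "Residual", "sum_sq": sse, "df": df_resid, "f_value": np.nan, "p_value": np.nan}
    )

    # pure error: replicate groups = identical actual settings within a block
    groups: dict[tuple, list[int]] = {}
    for i, p in enumerate(design.points):
        key = (p.block, tuple(np.round(p.actual_levels, 12)))
        groups.setdefault(key, []).append(i)
    ss_pe = 0.0
    df_pe = 0
    for idx in groups.values():
        if len(idx) > 1:
            g = y[idx]
            ss_pe += float(np.sum((g - g.mean()) ** 2))
            df_pe += len(idx) - 1
    if df_pe > 0:
        ss_lof = max(sse - ss_pe, 0.0)
        df_lof = df_resid - df_pe
        if df_lof > 0 and ss_pe > 0:
            f_lof = (ss_lof / df_lof) / (ss_pe / df_pe)
            p_lof = stats.f.sf(f_lof, df_lof, df_pe)
        else:
            f_lof, p_lof = np.nan, np.nan
        records.append(
            {"term": "Lack of Fit", "sum_sq": ss_lof, "df": df_lof, "f_value": f_lof, "p_value": p_lof}
        )
        records.append(
            {"term": "Pure Error", "sum_sq": ss_pe, "df": df_pe, "f_value": np.nan, "p_value": np.nan}
        )

    records.append(
        {"term": "Cor Total", "sum_sq": ss_total, "df": n - 1, "f_value": np.nan, "p_value": np.nan}
    )
    rows = pd.DataFrame.from_records(records).set_index("term")
    r_squared = 1.0 - sse / ss_total if ss_total > 0 else 1.0
    return AnovaTable(rows=rows, r_squared=r_squared)


@dataclass
class EffectEstimate:
    factor: str
    effect: float
    standard_error: float
    p_value: float
    significant: bool


def screen_effects(
    design: DesignMatrix, responses: ResponseTable, response_name: str, alpha_level: float = 0.05
) -> list[EffectEstimate]:
    """Plackett-Burman main-effect screening.

    Effect = mean response at +1 minus mean at -1 for each real factor.  The
    standard error is the root-mean-square of the dummy-column effects and the
    test a two-sided t with df = number of dummy columns.  With no dummy
    columns, effects are returned with NaN standard errors and p-values.
    Results are ranked by absolute effect size.
    """
    if design.design_kind != "plackett_burman":
        raise ValueError("screen_effects requires a Plackett-Burman design")
    y = responses.aligned_values(design, response_name)
    coded = design.coded_array()
    names = design.factor_names
    real = [i for i, nm in enumerate(names) if not nm.startswith("D")]
    dummy = [i for i, nm in enumerate(names) if nm.startswith("D")]

    def column_effect(j: int) -> float:
        col = coded[:, j]
        return float(y[col > 0].mean() - y[col < 0].mean())

    dummy_effects = np.array([column_effect(j) for j in dummy])
    if len(dummy):
        se = float(np.sqrt(np.mean(dummy_effects**2)))
    else:
        se = np.nan
    out = []
    for j in real:
        eff = column_effect(j)
        if len(dummy) and se > 0:
            t = eff / se
            p = float(2 * stats.t.sf(abs(t), df=len(dummy)))
        else:
            p = np.nan
        out.append(
            EffectEstimate(
                factor=names[j],
                effect=eff,
                standard_error=se,
                p_value=p,
                significant=bool(p < alpha_level) if np.isfinite(p) else False,
            )
        )
    out.sort(key=lambda e: abs(e.effect), reverse=True)
    return out
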