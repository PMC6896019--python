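"""Methylation-expression and clinical covariate associations.

Expression is modeled by ordinary least squares on a probe's beta-values,
with age kept as a covariate only when its own effect is significant
(two-sided alpha = 0.05); a Spearman rank correlation is reported alongside
the regression. Clinical covariates are tested with beta as the outcome
(numeric covariates by simple regression, categorical ones by one-way
ANOVA). The homogeneity of the tumor/normal signal across stages is probed
with a likelihood-ratio test of the stage x methylation interaction in a
logistic model of tissue class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

AGE_RETENTION_ALPHA = 0.05


@dataclass(frozen=True)
class AssocResult:
    probe_id: str
    dataset_code: str
    covariate: str
    slope: float
    p_value: float
    spearman_rho: float | None = None
    age_retained: bool | None = None

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p out of [0,1]: {self.p_value}")
        if self.spearman_rho is not None and not (-1.0 <= self.spearman_rho <= 1.0):
            raise ValueError(f"rho out of [-1,1]: {self.spearman_rho}")


def expr_assoc(
    beta: np.ndarray,
    expression: np.ndarray,
    age: np.ndarray | None = None,
    probe_id: str = "",
    dataset_code: str = "pooled",
) -> AssocResult:
    """OLS of expression on beta (age retained only if itself significant)."""
    beta = np.asarray(beta, dtype=float)
    expression = np.asarray(expression, dtype=float)
    mask = np.isfinite(beta) & np.isfinite(expression)
    if age is not None:
        age = np.asarray(age, dtype=float)
        mask &= np.isfinite(age)
    if mask.sum() < 10:
        raise ValueError(f"need >=10 complete pairs, got {mask.sum()}")
    b, e = beta[mask], expression[mask]
    if np.ptp(b) == 0:
        raise ValueError("constant beta column: slope undefined")

    age_retained = None
    X = sm.add_constant(b)
    if age is not None:
        a = age[mask]
        full = sm.OLS(e, sm.add_constant(np.column_stack([b, a]))).fit()
        age_retained = bool(full.pvalues[2] <= AGE_RETENTION_ALPHA)
        if age_retained:
            X = sm.add_constant(np.column_stack([b, a]))
    res = sm.OLS(e, X).fit()
    # single-parameter F-test on the beta slope (F = t^2)
    t = res.tvalues[1]
    p = float(stats.f.sf(t**2, 1, res.df_resid))
    rho = float(stats.spearmanr(b, e).statistic)
    return AssocResult(
        probe_id=probe_id, dataset_code=dataset_code, covariate="expression",
        slope=float(res.params[1]), p_value=p, spearman_rho=rho,
        age_retained=age_retained,
    )


def clinical_assoc(
    beta: np.ndarray,
    covariate: np.ndarray,
    name: str,
    probe_id: str = "",
    dataset_code: str = "pooled",
) -> AssocResult:
    """Beta-value as outcome; numeric covariates by OLS, categorical by ANOVA."""
    beta = np.asarray(beta, dtype=float)
    cov = np.asarray(covariate)
    numeric = np.issubdtype(cov.dtype, np.number)
    if numeric:
        mask = np.isfinite(beta) & np.isfinite(cov.astype(float))
    else:
        mask = np.isfinite(beta) & pd.notna(cov)
    b, c = beta[mask], cov[mask]

    if numeric:
        res = sm.OLS(b, sm.add_constant(c.astype(float))).fit()
        t = res.tvalues[1]
        p = float(stats.f.sf(t**2, 1, res.df_resid))
        return AssocResult(probe_id, dataset_code, name, float(res.params[1]), p)

    levels = pd.unique(c)
    if len(levels) < 2:
        raise ValueError(f"covariate {name!r} has a single level")
    groups = [b[c == lev] for lev in levels]
    f, p = stats.f_oneway(*groups)
    means = [g.mean() for g in groups]
    return AssocResult(
        probe_id, dataset_code, name,
        slope=float(max(means) - min(means)),  # effect size: group-mean span
        p_value=float(p),
    )


def stage_interaction_lrt(
    tissue: np.ndarray,
    beta: np.ndarray,
    stage: np.ndarray,
    stage_as_factor: bool = False,
) -> tuple[float, int, float]:
    """LRT of the stage x methylation interaction in a logistic tissue model.

    Compares tissue ~ beta + stage + beta:stage against tissue ~ beta + stage.
    Stage is coded numerically 1-4 by default (one interaction df); factor
    coding (3 interaction df) is available. Samples missing stage are dropped
    (complete-case); a warning is emitted when more than half are missing.
    """
    tissue = np.asarray(tissue, dtype=float)
    beta = np.asarray(beta, dtype=float)
    stage_arr = np.asarray(stage, dtype=float)
    mask = np.isfinite(tissue) & np.isfinite(beta) & np.isfinite(stage_arr)
    if mask.sum() < 0.5 * len(tissue):
        import warnings

        warnings.warn(
            "stage missing for >50% of samples; complete-case analysis",
            stacklevel=2,
        )
    y, b, s = tissue[mask], beta[mask], stage_arr[mask]

    if stage_as_factor:
        levels = np.unique(s)[1:]  # reference = lowest stage
        S = np.column_stack([(s == lev).astype(float) for lev in levels])
    else:
        S = s[:, None]
    inter = b[:, None] * S
    X_reduced = sm.add_constant(np.column_stack([b[:, None], S]))
    X_full = sm.add_constant(np.column_stack([b[:, None], S, inter]))

    fam = sm.families.Binomial()
    res_r = sm.GLM(y, X_reduced, family=fam).fit()
    res_f = sm.GLM(y, X_full, family=fam).fit()
    for res, label in ((res_r, "reduced"), (res_f, "full")):
        if not np.all(np.isfinite(res.params)):
            raise RuntimeError(f"{label} logistic model did not converge")
    lrt = max(0.0, 2.0 * (res_f.llf - res_r.llf))
    df = inter.shape[1]
    p = float(stats.chi2.sf(lrt, df)) if lrt > 0 else 1.0
    return float(lrt), df, p


def assoc_table(
    bm, meta, alpha: float = 0.05
) -> pd.DataFrame:
    """Expression association for every probe within every dataset."""
    rows = []
    by_type: dict[str, list] = {}
    for m in meta:
        by_type.setdefault(m.tumor_type, []).append(m)
    for code in sorted(by_type):
        ms = by_type[code]
        ids = [m.sample_id for m in ms]
        expr = np.array(
            [m.expression if m.expression is not None else np.nan for m in ms]
        )
        age = np.array(
            [m.age_at_diagnosis if m.age_at_diagnosis is not None else np.nan for m in ms]
        )
        if np.isfinite(expr).sum() < 10:
            import logging

            logging.getLogger(__name__).warning(
                "dataset %s: <10 complete expression pairs, skipped", code
            )
            continue
        sub = bm.values.loc[ids]
        for probe in bm.probe_ids:
            r = expr_assoc(
                sub[probe].to_numpy(), expr, age, probe_id=probe, dataset_code=code
            )
            rows.append(
                {
                    "probe_id": r.probe_id,
                    "dataset_code": r.dataset_code,
                    "slope": r.slope,
                    "p_value": r.p_value,
                    "spearman_rho": r.spearman_rho,
                    "significant": r.p_value <= alpha,
                    "spearman_agrees": (
                        stats.spearmanr(
                            sub[probe].to_numpy()[np.isfinite(expr)],
                            expr[np.isfinite(expr)],
                        ).pvalue
                        <= alpha
                    )
                    == (r.p_value <= alpha),
                }
            )
    return pd.DataFrame(rows)
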