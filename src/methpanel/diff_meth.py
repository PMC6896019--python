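"""Per-probe tumor-vs-normal differential methylation.

Each probe is tested within each dataset with a paired linear mixed model:
beta-value regressed on tissue class (NT vs TP) with a random intercept per
patient barcode, F-tested with a Satterthwaite small-sample denominator-df
correction (see :mod:`methpanel.lmm`). Unpaired samples are kept as singleton
random-effect groups. Tests run on beta-values directly, without M-value
transformation, and raw p-values are reported by default; an optional
Benjamini-Hochberg adjustment is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .data_model import BetaMatrix, SampleMeta
from .lmm import fit_random_intercept


class InsufficientDataError(ValueError):
    """A tissue class has too few samples to test."""


@dataclass(frozen=True)
class DiffMethResult:
    probe_id: str
    dataset_code: str
    mean_beta_nt: float
    mean_beta_tp: float
    direction: str  # "hyper", "hypo" or "ns"
    p_value: float
    test_statistic: float
    denominator_df: float
    converged: bool = True

    def __post_init__(self) -> None:
        if self.direction == "hyper" and not self.mean_beta_tp > self.mean_beta_nt:
            raise ValueError("hyper requires TP mean above NT mean")
        if self.direction == "hypo" and not self.mean_beta_tp < self.mean_beta_nt:
            raise ValueError("hypo requires TP mean below NT mean")


def test_probe(
    beta: pd.Series,
    meta: Sequence[SampleMeta],
    alpha: float = 0.05,
    dataset_code: str = "pooled",
) -> DiffMethResult:
    """Mixed-model F-test of tissue on one probe's beta-values.

    ``beta`` is indexed by sample_id; ``meta`` supplies tissue class and
    patient barcode. Missing beta-values are dropped.
    """
    by_id = {m.sample_id: m for m in meta}
    mask = beta.notna() & beta.index.isin(by_id)
    y = beta[mask].to_numpy(dtype=float)
    sel = [by_id[s] for s in beta.index[mask]]
    tissue = np.array([1.0 if m.tissue == "TP" else 0.0 for m in sel])
    groups = np.array([m.patient_barcode for m in sel])

    n_nt = int(np.sum(tissue == 0))
    n_tp = int(np.sum(tissue == 1))
    if n_nt < 2 or n_tp < 2:
        raise InsufficientDataError(
            f"{beta.name}/{dataset_code}: need >=2 samples per tissue class, "
            f"got NT={n_nt}, TP={n_tp}"
        )
    mean_nt = float(y[tissue == 0].mean())
    mean_tp = float(y[tissue == 1].mean())

    X = np.column_stack([np.ones_like(y), tissue])
    try:
        fit = fit_random_intercept(y, X, groups, test_index=1)
    except np.linalg.LinAlgError:
        return DiffMethResult(
            probe_id=str(beta.name), dataset_code=dataset_code,
            mean_beta_nt=mean_nt, mean_beta_tp=mean_tp, direction="ns",
            p_value=np.nan, test_statistic=np.nan, denominator_df=np.nan,
            converged=False,
        )

    # direction follows the model coefficient; in rare unbalanced-pairing
    # cases the GLS sign can contradict the raw mean difference, and no
    # confident call is made
    effect = fit.coef[1]
    if fit.pvalue <= alpha and effect > 0 and mean_tp > mean_nt:
        direction = "hyper"
    elif fit.pvalue <= alpha and effect < 0 and mean_tp < mean_nt:
        direction = "hypo"
    else:
        direction = "ns"
    return DiffMethResult(
        probe_id=str(beta.name),
        dataset_code=dataset_code,
        mean_beta_nt=mean_nt,
        mean_beta_tp=mean_tp,
        direction=direction,
        p_value=fit.pvalue,
        test_statistic=fit.fstat,
        denominator_df=fit.ddf,
        converged=fit.converged,
    )


test_probe.__test__ = False  # name collides with pytest's collection pattern


def differential_methylation(
    bm: BetaMatrix,
    meta: Sequence[SampleMeta],
    alpha: float = 0.05,
    adjust: bool = False,
) -> list[DiffMethResult]:
    """Test every probe within every dataset; optionally BH-adjust p-values."""
    by_type: dict[str, list[SampleMeta]] = {}
    for m in meta:
        by_type.setdefault(m.tumor_type, []).append(m)

    results: list[DiffMethResult] = []
    for code in sorted(by_type):
        sub_meta = by_type[code]
        ids = [m.sample_id for m in sub_meta if m.sample_id in bm.values.index]
        sub = bm.values.loc[ids]
        for probe in bm.probe_ids:
            results.append(test_probe(sub[probe], sub_meta, alpha, dataset_code=code))

    if adjust and results:
        ps = np.array([r.p_value for r in results])
        ok = np.isfinite(ps)
        adj = np.full_like(ps, np.nan)
        adj[ok] = multipletests(ps[ok], method="fdr_bh")[1]
        out = []
        for r, p_adj in zip(results, adj):
            sig = np.isfinite(p_adj) and p_adj <= alpha
            if sig:
                direction = "hyper" if r.mean_beta_tp > r.mean_beta_nt else "hypo"
            else:
                direction = "ns"
            out.append(
                DiffMethResult(
                    r.probe_id, r.dataset_code, r.mean_beta_nt, r.mean_beta_tp,
                    direction, float(p_adj), r.test_statistic, r.denominator_df,
                    r.converged,
                )
            )
        results = out
    return results


def count_directions(results: Sequence[DiffMethResult]) -> pd.DataFrame:
    """Per-dataset hyper/hypo/ns tallies; tallies sum to the probe count."""
    seen = set()
    for r in results:
        key = (r.probe_id, r.dataset_code)
        if key in seen:
            raise ValueError(f"duplicate result for probe/dataset {key}")
        seen.add(key)
    df = pd.DataFrame(
        {
            "dataset_code": [r.dataset_code for r in results],
            "direction": [r.direction for r in results],
        }
    )
    counts = (
        df.groupby(["dataset_code", "direction"])
        .size()
        .unstack(fill_value=0)
        .reindex(columns=["hyper", "hypo", "ns"], fill_value=0)
    )
    counts.columns.name = None
    return counts


def results_to_frame(results: Sequence[DiffMethResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "probe_id": [r.probe_id for r in results],
            "dataset_code": [r.dataset_code for r in results],
            "mean_beta_NT": [r.mean_beta_nt for r in results],
            "mean_beta_TP": [r.mean_beta_tp for r in results],
            "direction": [r.direction for r in results],
            "p_value": [r.p_value for r in results],
            "test_statistic": [r.test_statistic for r in results],
            "denominator_df": [r.denominator_df for r in results],
        }
    )
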