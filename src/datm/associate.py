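"""Downstream description of topics: prevalence, correlations, regression.

Topic prevalence is the fraction of each group's documents in which a topic
is present (in any amount); the prevalence ratio frac_b/frac_a compares the
two groups.  The loading-vs-prevalence check correlates per-topic semantic
loadings with prevalence ratios by Spearman rank.  Topic presence can also
be modeled by logistic regression on document covariates, reported as
adjusted odds ratios with Wald 95% intervals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .gist import TopicRecord

__all__ = ["prevalence", "loading_prevalence_correlation", "topic_logit"]


def _presence_frame(records: list[TopicRecord]) -> pd.DataFrame:
    if not records:
        raise ValueError("no topic records")
    K = len(records[0].presence)
    return pd.DataFrame(
        [r.presence for r in records],
        index=pd.Index([r.doc_id for r in records], name="doc_id"),
        columns=range(K),
    )


def prevalence(
    records: list[TopicRecord],
    metadata: pd.DataFrame,
    group_var: str,
    group_levels: tuple[str, str],
) -> pd.DataFrame:
    """Per-topic document counts, fractions and the b/a prevalence ratio.

    ``metadata`` must carry ``doc_id`` and the grouping variable for every
    record.  Topics absent from the reference group get a NaN ratio (flagged
    undefined rather than continuity-corrected).
    """
    pres = _presence_frame(records)
    meta = metadata.set_index("doc_id") if "doc_id" in metadata.columns else metadata
    missing = pres.index.difference(meta.index)
    if len(missing):
        raise ValueError(f"metadata missing for doc_ids {list(missing[:5])}")
    g = meta.loc[pres.index, group_var]
    lvl_a, lvl_b = group_levels
    unknown = set(g.unique()) - {lvl_a, lvl_b}
    if unknown:
        raise ValueError(f"unknown group level(s) {sorted(unknown)}")
    in_a, in_b = g == lvl_a, g == lvl_b
    n_a, n_b = int(in_a.sum()), int(in_b.sum())
    if n_a == 0 or n_b == 0:
        raise ValueError("both group levels need at least one document")
    rows = []
    for k in pres.columns:
        ca, cb = int(pres.loc[in_a.values, k].sum()), int(pres.loc[in_b.values, k].sum())
        fa, fb = ca / n_a, cb / n_b
        rows.append(
            {
                "topic_id": k,
                "n_group_a": ca,
                "n_group_b": cb,
                "frac_a": fa,
                "frac_b": fb,
                "ratio": fb / fa if fa > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def loading_prevalence_correlation(
    loadings: np.ndarray, ratios: np.ndarray
) -> tuple[float, float, int]:
    """Spearman rank correlation between topic loadings and prevalence ratios.

    Topics with undefined (NaN/inf) ratios are dropped; at least 3 usable
    pairs are required.  Returns (rho, two-sided p, n_used).  Ranks use
    average ties; the p-value is the standard large-sample t approximation.
    Spearman is invariant to monotone transforms, so raw and log ratios give
    identical results.
    """
    loadings = np.asarray(loadings, dtype=np.float64)
    ratios = np.asarray(ratios, dtype=np.float64)
    if loadings.shape != ratios.shape:
        raise ValueError("loadings and ratios must align")
    ok = np.isfinite(loadings) & np.isfinite(ratios)
    if ok.sum() < 3:
        raise ValueError(f"need >= 3 usable topic pairs, have {int(ok.sum())}")
    rho, p = stats.spearmanr(loadings[ok], ratios[ok])
    return float(rho), float(p), int(ok.sum())


def topic_logit(
    records: list[TopicRecord],
    metadata: pd.DataFrame,
    topic_id: int,
    covariates: list[str],
    reference_levels: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Logistic regression of binary topic presence on document covariates.

    Categorical covariates are dummy-coded against a documented reference
    level (``reference_levels``, else the lexically first level); numeric
    covariates enter linearly.  Fitting is delegated to a standard
    maximum-likelihood backend.  Returns one row per term with the adjusted
    odds ratio exp(beta) and Wald 95% CI; the frame's ``attrs`` carry n,
    convergence, and log-likelihood.  Degenerate outcomes (all 0 or all 1)
    and non-convergence raise/flag explicitly rather than returning silent
    output.
    """
    pres = _presence_frame(records)
    if topic_id not in pres.columns:
        raise ValueError(f"unknown topic_id {topic_id}")
    meta = metadata.set_index("doc_id") if "doc_id" in metadata.columns else metadata
    meta = meta.loc[pres.index]
    y = pres[topic_id].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("degenerate outcome: topic present in all or no documents")
    reference_levels = reference_levels or {}
    cols = []
    for cov in covariates:
        col = meta[cov]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.astype(float).rename(cov))
        else:
            levels = sorted(col.astype(str).unique())
            ref = reference_levels.get(cov, levels[0])
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} not found for {cov!r}")
            for lvl in levels:
                if lvl == ref:
                    continue
                cols.append((col.astype(str) == lvl).astype(float).rename(f"{cov}[{lvl} vs {ref}]"))
    X = sm.add_constant(pd.concat(cols, axis=1), has_constant="add")
    model = sm.Logit(y, X.to_numpy())
    try:
        fit = model.fit(disp=0, maxiter=200)
        converged = bool(fit.mle_retvals.get("converged", True))
    except Exception as exc:  # separation and similar pathologies
        raise RuntimeError(f"logistic fit failed: {exc}") from exc
    params, ci = fit.params, fit.conf_int(alpha=0.05)
    out = pd.DataFrame(
        {
            "term": X.columns,
            "coef": params,
            "aor": np.exp(params),
            "ci_low": np.exp(ci[:, 0]),
            "ci_high": np.exp(ci[:, 1]),
            "p": fit.pvalues,
        }
    )
    out.attrs["n"] = int(len(y))
    out.attrs["converged"] = converged
    out.attrs["llf"] = float(fit.llf)
    if not converged:
        out.attrs["warning"] = "maximum-likelihood fit did not converge"
    return out
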