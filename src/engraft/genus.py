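"""Pre/post change in genus-level relative abundances.

ASV proportions are collapsed to genus (sentinel "unclassified ..." labels
kept distinct), the tested genus set is the union of the healthy-reference
core genera (prevalence >= 55% of healthy samples by default) and a
configured list of potentially pathogenic genera, restricted to genera
found in at least 10% of recipient samples.  Per genus, the post-minus-pre
delta in relative abundance is regressed on the four host predictors with
Gaussian likelihood-ratio tests per term and Tukey-adjusted pairwise
contrasts for significant multi-level factors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datasets import AsvTable, CohortDataset
from .diversity import to_proportions
from .similarity import DELTA_PREDICTORS, _lrt_table, build_design

#: pathogenic genus list shipped as a configurable default — six genera
#: potentially pathogenic to felines
DEFAULT_PATHOGENIC_GENERA = (
    "Veillonella",
    "Desulfovibrio",
    "Escherichia",
    "Campylobacter",
    "Streptococcus",
    "Helicobacter",
)


def genus_abundance(table: AsvTable, taxonomy: pd.DataFrame) -> pd.DataFrame:
    """Samples x genera relative-abundance matrix (rows sum to 1)."""
    missing = [a for a in table.asv_ids if a not in taxonomy.index]
    if missing:
        raise KeyError(f"ASVs missing taxonomy: {missing[:5]} (+{max(0, len(missing) - 5)} more)")
    prop = to_proportions(table)
    genera = taxonomy.loc[prop.columns, "genus"]
    return prop.T.groupby(genera.values).sum().T


def _prevalent_genera(genus_prop: pd.DataFrame, prevalence: float) -> list[str]:
    frac = (genus_prop > 0).mean(axis=0)
    return sorted(frac.index[frac >= prevalence])


def core_genera(healthy_table: AsvTable, taxonomy: pd.DataFrame,
                prevalence: float = 0.55) -> list[str]:
    """Genera present in at least ``prevalence`` of healthy samples (inclusive)."""
    if healthy_table.shape[0] < 2:
        raise ValueError("core genus estimation needs >=2 healthy samples")
    return _prevalent_genera(genus_abundance(healthy_table, taxonomy), prevalence)


def prevalence_filter(recipient_table: AsvTable, taxonomy: pd.DataFrame,
                      genera: list[str], min_prev: float = 0.10) -> list[str]:
    """Subset of ``genera`` found in >= ``min_prev`` of recipient samples (pre+post pooled)."""
    prevalent = set(_prevalent_genera(genus_abundance(recipient_table, taxonomy), min_prev))
    return [g for g in genera if g in prevalent]


def delta_table(cohort: CohortDataset, genera: list[str]) -> pd.DataFrame:
    """Recipients x genera post-minus-pre relative-abundance deltas (fractions)."""
    gen = genus_abundance(cohort.table, cohort.taxonomy)
    rows = {}
    for cat in cohort.recipient_cats():
        pre = cohort.sample_of(cat, "recipient_pre")
        post = cohort.sample_of(cat, "recipient_post")
        rows[cat] = gen.loc[post].reindex(genera, fill_value=0.0) - \
            gen.loc[pre].reindex(genera, fill_value=0.0)
    out = pd.DataFrame.from_dict(rows, orient="index")[genera]
    out.index.name = "cat_id"
    return out


def tested_genera(cohort: CohortDataset, *, core_prevalence: float = 0.55,
                  min_recipient_prev: float = 0.10,
                  core: list[str] | None = None,
                  pathogenic: list[str] = DEFAULT_PATHOGENIC_GENERA) -> list[str]:
    """(core U pathogenic) genera surviving the recipient prevalence filter.

    ``core`` may be supplied directly (e.g. from an external reference
    list); otherwise it is derived from the cohort's healthy samples.
    """
    if core is None:
        healthy = cohort.samples_with_role("healthy")
        core = core_genera(cohort.table.select_samples(healthy), cohort.taxonomy,
                           core_prevalence)
    candidates = sorted(set(core) | set(pathogenic))
    recip = [s for role in ("recipient_pre", "recipient_post")
             for s in cohort.samples_with_role(role)]
    return prevalence_filter(cohort.table.select_samples(recip), cohort.taxonomy,
                             candidates, min_recipient_prev)


def fit_genus_models(deltas: pd.DataFrame, recipients_meta: pd.DataFrame,
                     predictors=DELTA_PREDICTORS, alpha: float = 0.05) -> pd.DataFrame:
    """Per-genus OLS of delta on the host predictors with per-term LRT p.

    Returns one row per (genus, term) with the likelihood-ratio chi-squared,
    p-value and a significance flag at ``alpha``.  No correction is applied
    across genera.
    """
    meta = recipients_meta.set_index("cat_id").loc[deltas.index]
    design = build_design(meta, predictors)
    rows = []
    for genus in deltas.columns:
        table = _lrt_table(deltas[genus].to_numpy(dtype=float), design)
        table.insert(0, "genus", genus)
        rows.append(table)
    out = pd.concat(rows, ignore_index=True)
    out["significant"] = out["p"] < alpha
    return out


def tukey_contrasts(deltas: pd.Series, recipients_meta: pd.DataFrame, factor: str,
                    predictors=DELTA_PREDICTORS) -> pd.DataFrame:
    """Pairwise level contrasts of ``factor`` from the fitted per-genus model.

    Differences between level-adjusted means, their standard errors, and
    p-values adjusted with the studentized-range distribution on the model's
    residual degrees of freedom.  For a 2-level factor the plain t-test
    contrast is returned (noted in the ``adjustment`` column).
    """
    meta = recipients_meta.set_index("cat_id").loc[deltas.index]
    design = build_design(meta, predictors)
    x = sm.add_constant(pd.concat(design.values(), axis=1), has_constant="add")
    fit = sm.OLS(deltas.to_numpy(dtype=float), x.to_numpy(dtype=float)).fit()
    cols = list(x.columns)
    levels = sorted(meta[factor].astype(str).unique())
    k = len(levels)
    if k < 2:
        raise ValueError(f"factor {factor!r} has a single level")

    # coefficient vector per level: baseline level has no dummy column
    def level_vec(level: str) -> np.ndarray:
        v = np.zeros(len(cols))
        name = f"{factor}_{level}"
        if name in cols:
            v[cols.index(name)] = 1.0
        return v

    cov = fit.cov_params()
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            c = level_vec(levels[j]) - level_vec(levels[i])
            diff = float(c @ fit.params)
            se = float(np.sqrt(c @ cov @ c))
            t = diff / se if se > 0 else 0.0
            if k == 2:
                p = float(2 * stats.t.sf(abs(t), fit.df_resid))
                adj = "t-test (2 levels)"
            else:
                p = float(stats.studentized_range.sf(abs(t) * np.sqrt(2.0), k,
                                                     fit.df_resid))
                adj = "tukey"
            rows.append({"level_a": levels[i], "level_b": levels[j],
                         "estimate": diff, "se": se, "statistic": t,
                         "p_adjusted": p, "adjustment": adj})
    return pd.DataFrame(rows)
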