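"""Matched-dyad change in similarity toward the healthy reference.

Each FMT recipient is paired with every healthy reference cat of
compatible age (within a tolerance, 1 year by default) and matching dry
kibble consumption.  For each dyad the change in fecal microbiome
similarity is

    delta = sim(post, healthy) - sim(pre, healthy)

where similarity is 1 - Bray-Curtis dissimilarity (bounded, the default)
or the negative Aitchison distance (an unbounded similarity surrogate).
Positive delta means the recipient's microbiome moved toward the healthy
reference after FMT.  Only recipient-vs-healthy comparisons enter;
recipient-vs-recipient and healthy-vs-healthy pairs are excluded by
construction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datasets import CohortDataset, DistanceMatrix
from .diversity import beta_diversity

logger = logging.getLogger("engraft")

DELTA_PREDICTORS = ("responder", "clinical_signs", "antibiotics", "kibble")


def match_dyads(recipients_meta: pd.DataFrame, healthy_meta: pd.DataFrame,
                *, age_tol: float = 1.0, match_kibble: bool = True) -> pd.DataFrame:
    """All qualifying (recipient cat, healthy sample) pairs, many-to-many.

    A dyad qualifies when |age difference| <= ``age_tol`` (inclusive) and,
    if ``match_kibble``, the two cats share their dry-kibble flag.
    Recipients with zero matches are reported in a coverage warning and
    absent from the output.  Ordering is deterministic (recipient then
    healthy id).
    """
    recipients_meta = recipients_meta.reset_index(drop=True)
    healthy_meta = healthy_meta.reset_index(drop=True)
    for frame, who in ((recipients_meta, "recipient"), (healthy_meta, "healthy")):
        if frame["age_years"].isna().any():
            bad = frame.loc[frame["age_years"].isna(), "sample_id"].tolist()
            raise ValueError(f"{who} ages missing for {bad}")
    rows = []
    unmatched = []
    for _, rec in recipients_meta.sort_values("cat_id").iterrows():
        cand = healthy_meta[
            (healthy_meta["age_years"] - rec["age_years"]).abs() <= age_tol]
        if match_kibble:
            cand = cand[cand["kibble"] == rec["kibble"]]
        if cand.empty:
            unmatched.append(rec["cat_id"])
            continue
        for _, h in cand.sort_values("sample_id").iterrows():
            rows.append({
                "cat_id": rec["cat_id"],
                "healthy_sample_id": h["sample_id"],
                "age_difference": float(abs(h["age_years"] - rec["age_years"])),
                "kibble": rec["kibble"],
            })
    if unmatched:
        logger.warning("dyad matching: %d recipient(s) with no compatible healthy "
                       "cat: %s", len(unmatched), ", ".join(unmatched))
    return pd.DataFrame(rows, columns=["cat_id", "healthy_sample_id",
                                       "age_difference", "kibble"])


def _similarity(distance: float, metric: str) -> float:
    return 1.0 - distance if metric == "bray_curtis" else -distance


def delta_similarity(cohort: CohortDataset, dyads: pd.DataFrame,
                     metric: str = "bray_curtis",
                     distance: DistanceMatrix | None = None) -> pd.DataFrame:
    """Per-dyad pre/post similarity to the healthy partner and their delta.

    Distances are computed over the union of recipient pre/post samples and
    healthy samples (or taken from a pre-computed ``distance`` matrix whose
    metric must match).  For Bray-Curtis, similarity = 1 - distance, so
    delta lies in [-1, 1]; for Aitchison the negative distance is used as a
    similarity surrogate.
    """
    if dyads.empty:
        return pd.DataFrame(columns=["cat_id", "healthy_sample_id", "age_difference",
                                     "kibble", "pre_similarity", "post_similarity",
                                     "delta", "metric"])
    if distance is None:
        needed = set(dyads["healthy_sample_id"])
        for cat in dyads["cat_id"].unique():
            needed.add(cohort.sample_of(cat, "recipient_pre"))
            needed.add(cohort.sample_of(cat, "recipient_post"))
        distance = beta_diversity(cohort.table.select_samples(sorted(needed)), metric)
    elif distance.metric != metric:
        raise ValueError(
            f"pre-computed matrix holds {distance.metric!r}, not {metric!r}")

    rows = []
    for _, dyad in dyads.iterrows():
        cat, healthy = dyad["cat_id"], dyad["healthy_sample_id"]
        pre = cohort.sample_of(cat, "recipient_pre")
        post = cohort.sample_of(cat, "recipient_post")
        s_pre = _similarity(distance.between(pre, healthy), metric)
        s_post = _similarity(distance.between(post, healthy), metric)
        rows.append({**dyad, "pre_similarity": s_pre, "post_similarity": s_post,
                     "delta": s_post - s_pre, "metric": metric})
    return pd.DataFrame(rows)


def group_delta_summary(deltas: pd.DataFrame, recipients_meta: pd.DataFrame,
                        factor: str, *, weighting: str = "dyad") -> pd.DataFrame:
    """Mean +/- standard error of delta per level of a host factor.

    ``weighting='dyad'`` averages over dyads (the default, matching one
    delta per recipient-healthy pair); ``'recipient'`` first averages each
    recipient's dyads, then averages recipients.  Empty levels are omitted
    with a warning.
    """
    if factor not in DELTA_PREDICTORS:
        raise ValueError(f"factor must be one of {DELTA_PREDICTORS}")
    if weighting not in ("dyad", "recipient"):
        raise ValueError("weighting must be 'dyad' or 'recipient'")
    meta = recipients_meta.set_index("cat_id")[factor]
    df = deltas.assign(level=deltas["cat_id"].map(meta))
    if weighting == "recipient":
        df = (df.groupby(["level", "cat_id"], as_index=False)["delta"].mean())
    present = set(df["level"].dropna())
    missing = set(meta.dropna().unique()) - present
    if missing:
        logger.warning("group_delta_summary: empty level(s) omitted: %s",
                       ", ".join(sorted(missing)))
    out = (df.groupby("level")["delta"]
           .agg(n="count", mean_delta="mean",
                se_delta=lambda x: x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else np.nan)
           .reset_index())
    return out


def _lrt_table(y: np.ndarray, design: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Gaussian OLS with per-term likelihood-ratio tests against drop-one models."""
    full_x = sm.add_constant(pd.concat(design.values(), axis=1), has_constant="add")
    if np.linalg.matrix_rank(full_x.to_numpy()) < full_x.shape[1]:
        raise ValueError(
            f"aliased (collinear) predictors among {sorted(design)}; "
            "drop or merge confounded terms")
    full = sm.OLS(y, full_x.to_numpy(dtype=float)).fit()
    n = len(y)
    rows = []
    for term, block in design.items():
        reduced_cols = pd.concat([b for t, b in design.items() if t != term], axis=1) \
            if len(design) > 1 else pd.DataFrame(index=block.index)
        red_x = sm.add_constant(reduced_cols, has_constant="add")
        red = sm.OLS(y, red_x.to_numpy(dtype=float)).fit()
        # Gaussian profile likelihood ratio: n * log(SSR_reduced / SSR_full);
        # a saturated/degenerate fit (zero residual SS in both) carries no evidence
        if full.ssr <= 1e-300:
            lr = 0.0 if red.ssr <= 1e-300 else np.inf
        else:
            lr = n * float(np.log(red.ssr / full.ssr))
        df_diff = block.shape[1]
        p = float(stats.chi2.sf(max(lr, 0.0), df_diff))
        rows.append({"term": term, "df": df_diff, "chi2": max(lr, 0.0), "p": p})
    return pd.DataFrame(rows)


def build_design(meta: pd.DataFrame, predictors=DELTA_PREDICTORS) -> dict[str, pd.DataFrame]:
    design = {}
    for term in predictors:
        col = meta[term].astype(str)
        if col.isna().any() or (col == "nan").any():
            raise ValueError(f"predictor {term!r} has missing values")
        if col.nunique() < 2:
            raise ValueError(f"predictor {term!r} has a single level")
        design[term] = pd.get_dummies(col, prefix=term, drop_first=True, dtype=float)
    return design


def delta_model(deltas: pd.DataFrame, recipients_meta: pd.DataFrame,
                predictors=DELTA_PREDICTORS) -> pd.DataFrame:
    """OLS of dyad deltas on the four host predictors with per-term LRT p.

    The Gaussian likelihood-ratio test compares the full model against the
    model with the term dropped (chi-squared, df = dropped columns).
    """
    meta = recipients_meta.set_index("cat_id")
    overlap = [c for c in predictors if c in deltas.columns]
    df = deltas.drop(columns=overlap).join(meta[list(predictors)], on="cat_id")
    design = build_design(df, predictors)
    return _lrt_table(df["delta"].to_numpy(dtype=float), design)
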