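"""Donor-to-recipient ASV engraftment quantification.

An ASV "engrafts" when it is present in the recipient's post-FMT sample and
in the assigned stool donor, but absent from the recipient's pre-FMT
sample.  The engraftment (sharing) rate divides the number of such ASVs by
the number of donor ASVs with the capacity to engraft — the donor pool
minus everything already shared pre-FMT:

    eligible  = D \\ P
    engrafted = (Q & D) \\ P
    rate      = |engrafted| / |eligible|

with D the donor presence set, P and Q the recipient pre- and post-FMT
presence sets.  Rates are kept on the [0, 1] scale internally and
percentages at presentation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import AsvTable, CohortDataset
from .permstats import kruskal_wallis

logger = logging.getLogger("engraft")

DONOR_COLLAPSE_MODES = ("union", "intersection")


@dataclass
class EngraftmentResult:
    """Per-recipient engraftment sets and rates plus cohort-level summary."""

    per_recipient: pd.DataFrame      # indexed by cat_id
    engrafted_sets: dict[str, set[str]]
    eligible_sets: dict[str, set[str]]

    def to_frame(self) -> pd.DataFrame:
        return self.per_recipient.reset_index(drop=True)

    def defined(self) -> pd.DataFrame:
        return self.per_recipient[self.per_recipient["rate"].notna()]

    def summary(self) -> dict[str, float]:
        rates = self.defined()["rate"]
        return {
            "n_recipients": int(len(rates)),
            "mean_rate": float(rates.mean()),
            "sd_rate": float(rates.std(ddof=1)) if len(rates) > 1 else 0.0,
            "min_rate": float(rates.min()),
            "max_rate": float(rates.max()),
            "mean_eligible": float(self.defined()["eligible_count"].mean()),
            "mean_engrafted": float(self.defined()["engrafted_count"].mean()),
        }


def presence_set(table: AsvTable, sample_ids: list[str] | str,
                 min_abundance: float = 0) -> set[str]:
    """ASVs with abundance strictly above ``min_abundance`` in any listed sample."""
    if isinstance(sample_ids, str):
        sample_ids = [sample_ids]
    if not sample_ids:
        raise ValueError("sample_ids must be non-empty")
    sub = table.select_samples(sample_ids).data
    present = (sub > min_abundance).any(axis=0)
    return set(present.index[present])


def donor_pool(cohort: CohortDataset, donor_id: str, *, collapse: str = "union",
               min_abundance: float = 0) -> set[str]:
    """Presence set of a donor identity across all of its samples.

    Multi-sample donors are collapsed by ``union`` (inclusive default) or
    ``intersection`` of the per-sample presence sets.
    """
    if collapse not in DONOR_COLLAPSE_MODES:
        raise ValueError(f"collapse must be one of {DONOR_COLLAPSE_MODES}")
    samples = cohort.donor_samples(donor_id)
    sets = [presence_set(cohort.table, s, min_abundance) for s in samples]
    out = set(sets[0])
    for s in sets[1:]:
        out = out | s if collapse == "union" else out & s
    return out


def engraftment_rate(cohort: CohortDataset, cat_id: str, *, collapse: str = "union",
                     min_abundance: float = 0) -> dict:
    """One recipient's engraftment bookkeeping (a row of the result table).

    ``rate`` is NaN (flagged) when the eligible set is empty.
    """
    meta = cohort.recipient_meta()
    if cat_id not in meta.index:
        raise KeyError(f"unknown recipient cat {cat_id!r}")
    donor_id = meta.loc[cat_id, "donor_id"]
    d = donor_pool(cohort, donor_id, collapse=collapse, min_abundance=min_abundance)
    p = presence_set(cohort.table, cohort.sample_of(cat_id, "recipient_pre"), min_abundance)
    q = presence_set(cohort.table, cohort.sample_of(cat_id, "recipient_post"), min_abundance)
    eligible = d - p
    engrafted = (q & d) - p
    row = {
        "cat_id": cat_id,
        "donor_id": donor_id,
        "donor_pool_size": len(d),
        "pre_shared_count": len(d & p),
        "eligible_count": len(eligible),
        "engrafted_count": len(engrafted),
        "rate": (len(engrafted) / len(eligible)) if eligible else np.nan,
        "_eligible": eligible,
        "_engrafted": engrafted,
    }
    if not eligible:
        logger.warning(
            "recipient %s: empty eligible donor set (donor %s entirely shared "
            "pre-FMT); rate undefined and excluded from summaries", cat_id, donor_id)
    return row


def cohort_engraftment(cohort: CohortDataset, *, collapse: str = "union",
                       min_abundance: float = 0) -> EngraftmentResult:
    """Engraftment rates for every recipient plus a cohort summary."""
    rows, engrafted_sets, eligible_sets = [], {}, {}
    for cat in cohort.recipient_cats():
        row = engraftment_rate(cohort, cat, collapse=collapse, min_abundance=min_abundance)
        eligible_sets[cat] = row.pop("_eligible")
        engrafted_sets[cat] = row.pop("_engrafted")
        rows.append(row)
    per_recipient = pd.DataFrame(rows).set_index("cat_id", drop=False)
    if per_recipient["rate"].notna().sum() == 0:
        raise ValueError("no recipient has a defined engraftment rate")
    return EngraftmentResult(per_recipient=per_recipient,
                             engrafted_sets=engrafted_sets,
                             eligible_sets=eligible_sets)


def donor_sharing_summary(result: EngraftmentResult) -> tuple[pd.DataFrame, tuple[float, float] | None]:
    """Per-donor rate distributions and a donor-identity Kruskal–Wallis test.

    Returns ``(per_donor_table, (H, p))``; the test is omitted (``None``)
    when only a single donor is represented.
    """
    defined = result.defined()
    per_donor = (defined.groupby("donor_id")["rate"]
                 .agg(n_recipients="count", mean_rate="mean", median_rate="median")
                 .reset_index())
    if per_donor.shape[0] < 2:
        return per_donor, None
    h, p = kruskal_wallis(defined["rate"].to_numpy(), defined["donor_id"].to_numpy())
    return per_donor, (h, p)


def engrafted_taxonomy_breakdown(result: EngraftmentResult,
                                 taxonomy: pd.DataFrame) -> pd.DataFrame:
    """Genus-level percentage breakdown of all engrafted (recipient, ASV) events.

    Events are pooled across recipients; sentinel "unclassified ..." labels
    stay distinct.  Percentages sum to 100 (empty frame when nothing
    engrafted anywhere).
    """
    events: list[str] = []
    missing: set[str] = set()
    for cat, asvs in result.engrafted_sets.items():
        for asv in asvs:
            if asv not in taxonomy.index:
                missing.add(asv)
            else:
                events.append(taxonomy.loc[asv, "genus"])
    if missing:
        raise KeyError(f"engrafted ASVs missing taxonomy: {sorted(missing)}")
    if not events:
        return pd.DataFrame(columns=["genus", "n_events", "percent"])
    counts = pd.Series(events).value_counts()
    out = counts.rename("n_events").rename_axis("genus").reset_index()
    out["percent"] = 100.0 * out["n_events"] / out["n_events"].sum()
    return out


def commonly_shared_asvs(result: EngraftmentResult, taxonomy: pd.DataFrame,
                         min_recipients: int = 10) -> pd.DataFrame:
    """ASVs that engrafted in strictly more than ``min_recipients`` recipients.

    Sorted by descending recipient count, ties broken by ASV id.
    """
    tally: dict[str, int] = {}
    for asvs in result.engrafted_sets.values():
        for asv in asvs:
            tally[asv] = tally.get(asv, 0) + 1
    rows = [
        {"asv_id": asv, "n_recipients": n,
         "genus": taxonomy.loc[asv, "genus"] if asv in taxonomy.index else None}
        for asv, n in tally.items() if n > min_recipients
    ]
    out = pd.DataFrame(rows, columns=["asv_id", "n_recipients", "genus"])
    return out.sort_values(["n_recipients", "asv_id"],
                           ascending=[False, True]).reset_index(drop=True)
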