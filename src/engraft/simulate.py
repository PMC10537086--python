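"""Synthetic FMT cohort generator with known engraftment ground truth.

Emulates the data structure of an oral-capsule FMT study in domestic cats:
paired pre/post recipient samples, stool donors (some of which are pooled
pairs of cohabiting cats, some sampled repeatedly), and a healthy reference
population with age and diet metadata.  Communities are symmetric-Dirichlet
compositions over host-specific ASV subsets; reads are multinomial draws.
Engraftment is simulated at ASV presence level: each donor ASV absent from
the recipient's pre-FMT community engrafts independently with probability
``true_engraftment_prob``, inheriting its abundance from the donor
composition.

The generator's defaults mirror the study conditions (46 recipients, 10
donor cats forming 8 donor identities with 20 samples, 113 healthy cats);
every draw is controlled by a single seed, so output is bit-for-bit
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .datasets import (
    AsvTable,
    CohortDataset,
    SampleRecord,
    metadata_frame,
    unclassified_label,
)

# Genus pool used for the synthetic taxonomy.  Weights loosely follow
# feline fecal communities: Prevotella 9 / Bacteroides / Collinsella /
# Blautia / Peptoclostridium dominate, a tail of rarer genera plus
# sentinel labels for ASVs unresolved at genus level.
_GENUS_POOL: list[tuple[str, float]] = [
    ("Prevotella 9", 0.10),
    ("Bacteroides", 0.08),
    ("Collinsella", 0.06),
    ("Blautia", 0.06),
    ("Peptoclostridium", 0.05),
    ("Clostridium", 0.05),
    ("Megamonas", 0.04),
    ("Subdoligranulum", 0.04),
    ("Negativibacillus", 0.03),
    ("Butyricoccus", 0.03),
    ("Peptococcus", 0.03),
    ("Ruminococcus", 0.03),
    ("Fusobacterium", 0.03),
    ("Lachnoclostridium", 0.03),
    ("Enterococcus", 0.02),
    ("Megasphaera", 0.02),
    ("Faecalibacterium", 0.02),
    ("Bifidobacterium", 0.02),
    ("Dialister", 0.02),
    ("Alloprevotella", 0.02),
    ("Catenibacterium", 0.02),
    ("Holdemanella", 0.02),
    ("Veillonella", 0.02),
    ("Desulfovibrio", 0.02),
    ("Escherichia", 0.02),
    ("Campylobacter", 0.01),
    ("Streptococcus", 0.01),
    ("Helicobacter", 0.01),
    (unclassified_label("Lachnospiraceae"), 0.05),
    (unclassified_label("Oscillospirales"), 0.03),
    (unclassified_label("Butyricicoccaceae"), 0.02),
    (unclassified_label("Oscillospiraceae"), 0.02),
]

# coarse upper ranks per genus; anything unlisted falls back to a generic
# Firmicutes lineage (family taken from sentinel labels where applicable)
_LINEAGES: dict[str, tuple[str, str, str, str]] = {
    "Prevotella 9": ("Bacteroidota", "Bacteroidia", "Bacteroidales", "Prevotellaceae"),
    "Alloprevotella": ("Bacteroidota", "Bacteroidia", "Bacteroidales", "Prevotellaceae"),
    "Bacteroides": ("Bacteroidota", "Bacteroidia", "Bacteroidales", "Bacteroidaceae"),
    "Collinsella": ("Actinobacteriota", "Coriobacteriia", "Coriobacteriales", "Coriobacteriaceae"),
    "Bifidobacterium": ("Actinobacteriota", "Actinobacteria", "Bifidobacteriales", "Bifidobacteriaceae"),
    "Fusobacterium": ("Fusobacteriota", "Fusobacteriia", "Fusobacteriales", "Fusobacteriaceae"),
    "Escherichia": ("Proteobacteria", "Gammaproteobacteria", "Enterobacterales", "Enterobacteriaceae"),
    "Desulfovibrio": ("Desulfobacterota", "Desulfovibrionia", "Desulfovibrionales", "Desulfovibrionaceae"),
    "Campylobacter": ("Campylobacterota", "Campylobacteria", "Campylobacterales", "Campylobacteraceae"),
    "Helicobacter": ("Campylobacterota", "Campylobacteria", "Campylobacterales", "Helicobacteraceae"),
    "Veillonella": ("Firmicutes", "Negativicutes", "Veillonellales", "Veillonellaceae"),
    "Megamonas": ("Firmicutes", "Negativicutes", "Veillonellales", "Selenomonadaceae"),
    "Megasphaera": ("Firmicutes", "Negativicutes", "Veillonellales", "Veillonellaceae"),
    "Dialister": ("Firmicutes", "Negativicutes", "Veillonellales", "Veillonellaceae"),
    "Enterococcus": ("Firmicutes", "Bacilli", "Lactobacillales", "Enterococcaceae"),
    "Streptococcus": ("Firmicutes", "Bacilli", "Lactobacillales", "Streptococcaceae"),
}

_DEFAULT_LINEAGE = ("Firmicutes", "Clostridia", "Lachnospirales", "Lachnospiraceae")

#: default composition multipliers per host group (applied genus-wise to
#: both pre and post recipient communities before renormalization)
DEFAULT_COVARIATE_EFFECTS: dict[str, dict[str, dict[str, float]]] = {
    "clinical_signs": {
        "diarrhea": {"Prevotella 9": 2.0, "Escherichia": 1.5},
        "vomiting_diarrhea": {"Prevotella 9": 1.8, "Veillonella": 1.5},
        "constipation": {"Collinsella": 2.0, "Negativibacillus": 1.5},
        "vomiting_constipation": {"Collinsella": 1.8, "Desulfovibrio": 1.5},
    },
    "kibble": {
        "yes": {"Blautia": 1.6, "Peptoclostridium": 0.7},
    },
}

# marginal frequencies of the host covariates among recipients
_SIGN_PROBS = {"diarrhea": 0.41, "constipation": 0.17,
               "vomiting_diarrhea": 0.33, "vomiting_constipation": 0.09}
_P_MALE = 0.56
_P_ANTIBIOTICS = 0.52
_P_KIBBLE = 0.56
_P_RESPONDER = 0.60
_P_HEALTHY_KIBBLE = 0.70


@dataclass
class SimulationConfig:
    """Parameters of the synthetic FMT cohort.

    ``true_engraftment_prob`` may be a scalar or a per-recipient sequence
    (recipient ``i`` is assigned donor identity ``i mod n_identities``, so
    per-donor engraftment effects can be planted through the vector).
    ``noiseless`` replaces multinomial read sampling with a deterministic
    deep rendering in which every community member is guaranteed ≥1 read —
    used by truth-consistency tests.
    """

    n_recipients: int = 46
    n_donors: int = 10                  # donor cats
    n_pooled_donors: int = 2            # pairs of cohabiting cats merged 50:50
    n_healthy: int = 113
    asv_pool_size: int = 800
    donor_richness: int = 350
    recipient_richness: int = 250
    healthy_richness: int = 250
    reads_per_sample_mean: float = 50_000.0
    reads_dispersion: float = 0.25      # lognormal sigma of library size
    dirichlet_concentration: float = 0.7
    true_engraftment_prob: float | Sequence[float] = 0.13
    pre_donor_overlap: float = 0.35
    covariate_effects: Mapping[str, Mapping[str, Mapping[str, float]]] = field(
        default_factory=lambda: DEFAULT_COVARIATE_EFFECTS)
    post_covariate_effects: Mapping[str, Mapping[str, Mapping[str, float]]] = field(
        default_factory=dict)           # post-only shifts, for planted-effect tests
    age_range: tuple[float, float] = (1.0, 19.0)
    donor_sample_counts: Sequence[int] | None = None
    noiseless: bool = False
    seed: int = 0

    def __post_init__(self):
        if min(self.n_recipients, self.n_donors, self.n_healthy, self.asv_pool_size) < 1:
            raise ValueError("all cohort sizes must be >= 1")
        if self.n_donors <= 2 * self.n_pooled_donors and self.n_pooled_donors > 0:
            if self.n_donors < 2 * self.n_pooled_donors:
                raise ValueError("pooled donors require 2 cats each")
        if not (0.0 <= self.pre_donor_overlap <= 1.0):
            raise ValueError("pre_donor_overlap must be in [0, 1]")
        p = np.atleast_1d(np.asarray(self.true_engraftment_prob, dtype=float))
        if ((p < 0) | (p > 1)).any():
            raise ValueError("true_engraftment_prob must lie in [0, 1]")
        if p.size not in (1, self.n_recipients):
            raise ValueError(
                "true_engraftment_prob must be scalar or length n_recipients")
        if self.donor_richness > self.asv_pool_size:
            raise ValueError("donor_richness exceeds the ASV pool")

    @property
    def n_identities(self) -> int:
        """Number of donor identities (each pooled pair counts once)."""
        return self.n_donors - self.n_pooled_donors

    def engraftment_probs(self) -> np.ndarray:
        p = np.atleast_1d(np.asarray(self.true_engraftment_prob, dtype=float))
        if p.size == 1:
            p = np.repeat(p, self.n_recipients)
        return p


@dataclass
class SyntheticTruth:
    """Ground truth recorded during generation, for parameter-recovery tests."""

    eligible: dict[str, set[str]]       # cat_id -> donor ASVs absent pre-FMT
    engrafted: dict[str, set[str]]      # cat_id -> truly engrafted ASVs
    donor_of: dict[str, str]            # cat_id -> donor identity
    group_effects: dict
    seed: int

    def realized_fraction(self, cat_id: str) -> float:
        return len(self.engrafted[cat_id]) / len(self.eligible[cat_id])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cat in sorted(self.eligible):
            rows.append({
                "cat_id": cat,
                "donor_id": self.donor_of[cat],
                "n_eligible": len(self.eligible[cat]),
                "n_engrafted": len(self.engrafted[cat]),
                "realized_fraction": self.realized_fraction(cat),
                "engrafted_asvs": ",".join(sorted(self.engrafted[cat])),
            })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _make_taxonomy(asv_ids: list[str], rng: np.random.Generator) -> pd.DataFrame:
    names = [g for g, _ in _GENUS_POOL]
    weights = np.array([w for _, w in _GENUS_POOL])
    weights = weights / weights.sum()
    genera = rng.choice(names, size=len(asv_ids), p=weights)
    rows = []
    for asv, genus in zip(asv_ids, genera):
        phylum, cls, order, family = _LINEAGES.get(genus, _DEFAULT_LINEAGE)
        rows.append({"asv_id": asv, "domain": "Bacteria", "phylum": phylum,
                     "class": cls, "order": order, "family": family, "genus": genus})
    return pd.DataFrame(rows).set_index("asv_id")


def _composition(rng: np.random.Generator, pool: np.ndarray, richness: int,
                 conc: float, n_asvs: int) -> np.ndarray:
    """Dirichlet composition over a random subset; returns dense length-n vector."""
    support = rng.choice(pool, size=min(richness, pool.size), replace=False)
    comp = np.zeros(n_asvs)
    comp[support] = rng.dirichlet(np.full(support.size, conc))
    return comp


def _apply_genus_effects(comp: np.ndarray, genus_of: np.ndarray,
                         multipliers: Mapping[str, float]) -> np.ndarray:
    if not multipliers:
        return comp
    out = comp.copy()
    for genus, mult in multipliers.items():
        out[genus_of == genus] *= mult
    s = out.sum()
    return out / s if s > 0 else out


def _collect_multipliers(effects, record: SampleRecord) -> dict[str, float]:
    mult: dict[str, float] = {}
    for factor, levels in effects.items():
        level = getattr(record, factor, None)
        if level is not None and level in levels:
            for genus, m in levels[level].items():
                mult[genus] = mult.get(genus, 1.0) * m
    return mult


def _draw_reads(rng: np.random.Generator, comp: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    if cfg.noiseless:
        depth = int(cfg.reads_per_sample_mean)
        counts = np.rint(comp * depth).astype(np.int64)
        counts[(comp > 0) & (counts == 0)] = 1  # guarantee presence of all members
        return counts
    mu = np.log(cfg.reads_per_sample_mean) - cfg.reads_dispersion ** 2 / 2.0
    library = max(1000, int(np.round(rng.lognormal(mu, cfg.reads_dispersion))))
    return rng.multinomial(library, comp)


def _default_sample_counts(cfg: SimulationConfig) -> list[int]:
    # study shape: four 1-sample donors, one with 2, one with 6; pools 3 and 5
    n_ind = cfg.n_identities - cfg.n_pooled_donors
    if n_ind == 6 and cfg.n_pooled_donors == 2:
        return [1, 1, 1, 1, 2, 6, 3, 5]
    return [2] * cfg.n_identities


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def generate_tree(asv_ids: Sequence[str], seed: int) -> TreeNode:
    """Random rooted bifurcating tree over ``asv_ids`` with positive branch lengths.

    Built by repeated random joins (a coalescent-style topology); branch
    lengths are exponential with a small floor so every edge is positive.
    Deterministic under ``seed``.
    """
    ids = list(asv_ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 ASV ids to build a tree")
    rng = np.random.default_rng(seed)
    nodes = [f"{i}:{{:.6f}}".format(rng.exponential(0.5) + 0.01) for i in ids]
    # work on newick fragments; each join wraps two fragments into a clade
    frags = nodes
    while len(frags) > 1:
        i, j = sorted(rng.choice(len(frags), size=2, replace=False))
        bl = rng.exponential(0.5) + 0.01
        merged = f"({frags[i]},{frags[j]}):{bl:.6f}"
        frags = [f for k, f in enumerate(frags) if k not in (i, j)] + [merged]
    newick = frags[0]
    # strip the root's branch length and terminate
    newick = newick[: newick.rfind(":")] + ";"
    return TreeNode.read([newick])


def generate_cohort(config: SimulationConfig) -> tuple[CohortDataset, SyntheticTruth]:
    """Generate a full synthetic cohort and its engraftment ground truth."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_asvs = cfg.asv_pool_size
    asv_ids = [f"ASV{i:05d}" for i in range(n_asvs)]
    taxonomy = _make_taxonomy(asv_ids, rng)
    genus_of = taxonomy["genus"].to_numpy()
    pool = np.arange(n_asvs)
    conc = cfg.dirichlet_concentration

    records: list[SampleRecord] = []
    count_rows: dict[str, np.ndarray] = {}

    # ---- donors ----------------------------------------------------------
    n_ident = cfg.n_identities
    n_ind = n_ident - cfg.n_pooled_donors
    identity_ids = [f"D{i + 1}" for i in range(n_ident)]
    cat_comps: list[np.ndarray] = [
        _composition(rng, pool, cfg.donor_richness, conc, n_asvs)
        for _ in range(cfg.n_donors)
    ]
    identity_comp: dict[str, np.ndarray] = {}
    cat_cursor = 0
    for k, ident in enumerate(identity_ids):
        if k < n_ind:
            identity_comp[ident] = cat_comps[cat_cursor]
            cat_cursor += 1
        else:  # pooled pair mixed 50:50 before normalization
            mix = 0.5 * cat_comps[cat_cursor] + 0.5 * cat_comps[cat_cursor + 1]
            identity_comp[ident] = mix / mix.sum()
            cat_cursor += 2

    sample_counts = list(cfg.donor_sample_counts or _default_sample_counts(cfg))
    if len(sample_counts) != n_ident:
        raise ValueError("donor_sample_counts must have one entry per donor identity")
    for ident, n_s in zip(identity_ids, sample_counts):
        for s in range(n_s):
            sid = f"{ident}_s{s + 1}"
            count_rows[sid] = _draw_reads(rng, identity_comp[ident], cfg)
            records.append(SampleRecord(
                sample_id=sid, cat_id=ident, role="donor", donor_id=ident,
                age_years=round(float(np.clip(rng.normal(4.9, 3.4), 1.0, 15.0)), 1),
                sex=("M" if rng.random() < 0.5 else "F"),
                antibiotics="no", kibble=("yes" if rng.random() < 0.5 else "no"),
                fecal_score=int(rng.integers(3, 5)),
            ))

    # ---- recipients ------------------------------------------------------
    probs = cfg.engraftment_probs()
    sign_names = list(_SIGN_PROBS)
    sign_p = np.array([_SIGN_PROBS[s] for s in sign_names])
    sign_p = sign_p / sign_p.sum()

    eligible_truth: dict[str, set[str]] = {}
    engrafted_truth: dict[str, set[str]] = {}
    donor_of: dict[str, str] = {}
    recipient_ages = []

    k_overlap = int(round(cfg.pre_donor_overlap * cfg.recipient_richness))
    for i in range(cfg.n_recipients):
        cat = f"C{i + 1:02d}"
        ident = identity_ids[i % n_ident]
        donor_of[cat] = ident
        donor_support = np.flatnonzero(identity_comp[ident])

        overlap = rng.choice(donor_support, size=min(k_overlap, donor_support.size),
                             replace=False)
        outside = np.setdiff1d(pool, donor_support, assume_unique=False)
        n_rest = cfg.recipient_richness - overlap.size
        rest = rng.choice(outside, size=min(n_rest, outside.size), replace=False)
        support = np.concatenate([overlap, rest])
        pre = np.zeros(n_asvs)
        pre[support] = rng.dirichlet(np.full(support.size, conc))

        eligible = np.setdiff1d(donor_support, support)
        if eligible.size == 0:
            raise ValueError(
                f"recipient {cat}: empty eligible donor set "
                "(pre_donor_overlap too high relative to donor richness)")
        engraft_mask = rng.random(eligible.size) < probs[i]
        engrafted = eligible[engraft_mask]
        post = pre.copy()
        post[engrafted] += identity_comp[ident][engrafted]
        post = post / post.sum()

        eligible_truth[cat] = {asv_ids[j] for j in eligible}
        engrafted_truth[cat] = {asv_ids[j] for j in engrafted}

        age = round(float(np.clip(rng.normal(10.23, 4.03), *cfg.age_range)), 1)
        recipient_ages.append(age)
        meta_common = dict(
            cat_id=cat, donor_id=ident, age_years=age,
            sex=("M" if rng.random() < _P_MALE else "F"),
            clinical_signs=str(rng.choice(sign_names, p=sign_p)),
            responder=("responder" if rng.random() < _P_RESPONDER else "non_responder"),
            antibiotics=("yes" if rng.random() < _P_ANTIBIOTICS else "no"),
            kibble=("yes" if rng.random() < _P_KIBBLE else "no"),
        )
        rec_pre = SampleRecord(sample_id=f"{cat}_pre", role="recipient_pre",
                               fecal_score=None, **meta_common)
        # fecal score loosely tracks the clinical sign pre-FMT, normalizes post
        sign = meta_common["clinical_signs"]
        pre_score = {"diarrhea": 7, "vomiting_diarrhea": 6,
                     "constipation": 1, "vomiting_constipation": 2}[sign]
        rec_pre.fecal_score = pre_score
        post_score = int(rng.integers(3, 5)) if meta_common["responder"] == "responder" else pre_score
        rec_post = SampleRecord(sample_id=f"{cat}_post", role="recipient_post",
                                fecal_score=post_score, **meta_common)

        mult = _collect_multipliers(cfg.covariate_effects, rec_pre)
        pre_adj = _apply_genus_effects(pre, genus_of, mult)
        post_adj = _apply_genus_effects(post, genus_of, mult)
        post_adj = _apply_genus_effects(
            post_adj, genus_of, _collect_multipliers(cfg.post_covariate_effects, rec_post))

        count_rows[rec_pre.sample_id] = _draw_reads(rng, pre_adj, cfg)
        count_rows[rec_post.sample_id] = _draw_reads(rng, post_adj, cfg)
        records.extend([rec_pre, rec_post])

    # ---- healthy reference ----------------------------------------------
    age_lo, age_hi = min(recipient_ages), max(recipient_ages)
    for i in range(cfg.n_healthy):
        sid = f"H{i + 1:03d}"
        comp = _composition(rng, pool, cfg.healthy_richness, conc, n_asvs)
        rec = SampleRecord(
            sample_id=sid, cat_id=sid, role="healthy",
            age_years=round(float(rng.uniform(age_lo, age_hi)), 1),
            sex=("F" if rng.random() < 0.56 else "M"),
            antibiotics="no",
            kibble=("yes" if rng.random() < _P_HEALTHY_KIBBLE else "no"),
            fecal_score=int(rng.integers(3, 5)),
        )
        mult = _collect_multipliers(cfg.covariate_effects, rec)
        count_rows[sid] = _draw_reads(rng, _apply_genus_effects(comp, genus_of, mult), cfg)
        records.append(rec)

    counts = pd.DataFrame.from_dict(count_rows, orient="index", columns=asv_ids)
    counts.index.name = "sample_id"
    table = AsvTable(counts)
    tree = generate_tree(asv_ids, seed=int(rng.integers(0, 2**31 - 1)))
    cohort = CohortDataset(table=table, taxonomy=taxonomy,
                           metadata=metadata_frame(records), tree=tree)
    truth = SyntheticTruth(
        eligible=eligible_truth, engrafted=engrafted_truth, donor_of=donor_of,
        group_effects={"covariate_effects": dict(cfg.covariate_effects),
                       "post_covariate_effects": dict(cfg.post_covariate_effects)},
        seed=cfg.seed,
    )
    return cohort, truth
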