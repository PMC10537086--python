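import pandas as pd
import pytest

from engraft.datasets import AsvTable, CohortDataset, SampleRecord, metadata_frame
from engraft.simulate import SimulationConfig, generate_cohort


def make_taxonomy(asv_genus: dict[str, str]) -> pd.DataFrame:
    rows = []
    for asv, genus in asv_genus.items():
        rows.append({"asv_id": asv, "domain": "Bacteria", "phylum": "Firmicutes",
                     "class": "Clostridia", "order": "Lachnospirales",
                     "family": "Lachnospiraceae", "genus": genus})
    return pd.DataFrame(rows).set_index("asv_id")


def build_cohort(counts: dict[str, dict[str, int]], records: list[SampleRecord],
                 genus: dict[str, str] | None = None, tree=None) -> CohortDataset:
    """Assemble a hand-specified cohort; taxonomy defaults to one genus per ASV."""
    table = pd.DataFrame(counts).T.fillna(0).astype(int)
    table = table.loc[[r.sample_id for r in records]]
    asvs = list(table.columns)
    genus = genus or {a: f"Genus_{a}" for a in asvs}
    return CohortDataset(
        table=AsvTable(table),
        taxonomy=make_taxonomy(genus),
        metadata=metadata_frame(records),
        tree=tree,
    )


@pytest.fixture
def tiny_cohort() -> CohortDataset:
    """3 recipients (2 donors), 4 healthy cats, 6 ASVs with hand-set counts."""
    asvs = ["a", "b", "c", "d", "e", "f"]
    counts = {
        "D1_s1": dict(zip(asvs, [50, 40, 30, 0, 0, 0])),
        "D2_s1": dict(zip(asvs, [0, 0, 30, 40, 50, 0])),
        "D2_s2": dict(zip(asvs, [0, 0, 25, 45, 0, 10])),
        "C1_pre": dict(zip(asvs, [60, 0, 0, 0, 0, 40])),
        "C1_post": dict(zip(asvs, [50, 30, 0, 0, 0, 20])),
        "C2_pre": dict(zip(asvs, [0, 0, 70, 0, 0, 30])),
        "C2_post": dict(zip(asvs, [0, 0, 60, 25, 0, 15])),
        "C3_pre": dict(zip(asvs, [80, 20, 0, 0, 0, 0])),
        "C3_post": dict(zip(asvs, [70, 20, 10, 0, 0, 0])),
        "H1": dict(zip(asvs, [30, 30, 20, 20, 0, 0])),
        "H2": dict(zip(asvs, [0, 20, 30, 30, 20, 0])),
        "H3": dict(zip(asvs, [25, 25, 25, 25, 0, 0])),
        "H4": dict(zip(asvs, [10, 0, 0, 40, 40, 10])),
    }
    records = [
        SampleRecord("D1_s1", "D1", "donor", "D1", 5.0, "M", antibiotics="no", kibble="yes"),
        SampleRecord("D2_s1", "D2", "donor", "D2", 4.0, "F", antibiotics="no", kibble="no"),
        SampleRecord("D2_s2", "D2", "donor", "D2", 4.0, "F", antibiotics="no", kibble="no"),
    ]
    for cat, donor, age, sign, resp, abx, kib in [
        ("C1", "D1", 5.0, "diarrhea", "responder", "yes", "yes"),
        ("C2", "D2", 8.0, "constipation", "non_responder", "no", "no"),
        ("C3", "D1", 3.5, "vomiting_diarrhea", "responder", "no", "yes"),
    ]:
        for role in ("recipient_pre", "recipient_post"):
            suffix = "pre" if role == "recipient_pre" else "post"
            records.append(SampleRecord(
                f"{cat}_{suffix}", cat, role, donor, age, "M",
                clinical_signs=sign, responder=resp, antibiotics=abx, kibble=kib))
    for sid, age, kib in [("H1", 5.5, "yes"), ("H2", 8.2, "no"),
                          ("H3", 4.4, "yes"), ("H4", 12.0, "no")]:
        records.append(SampleRecord(sid, sid, "healthy", None, age, "F",
                                    antibiotics="no", kibble=kib))
    return build_cohort(counts, records,
                        genus={"a": "Prevotella 9", "b": "Blautia", "c": "Collinsella",
                               "d": "Bacteroides", "e": "Escherichia", "f": "Megamonas"})


SMALL_SIM = dict(
    n_recipients=12, n_donors=6, n_pooled_donors=1, n_healthy=24,
    asv_pool_size=240, donor_richness=100, recipient_richness=80,
    healthy_richness=80, reads_per_sample_mean=20_000.0,
    donor_sample_counts=[1, 2, 1, 3, 2],
)


@pytest.fixture(scope="session")
def sim_cohort():
    """A small simulated cohort shared across tests (seed-fixed)."""
    cfg = SimulationConfig(seed=11, **SMALL_SIM)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def star_tree():
    from skbio import TreeNode
    return TreeNode.read(["(a:1,b:1,c:1,d:1,e:1);"])
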