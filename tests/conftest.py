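import pytest

from barcodeval import LocusAlignment, MultiLocusDataset, SpecimenRecord
from barcodeval import generate, paper_preset


def make_dataset(rows_by_locus, species):
    """Build a MultiLocusDataset from {locus: [(id, seq), ...]} and labels."""
    all_ids = []
    for rows in rows_by_locus.values():
        for sid, _ in rows:
            if sid not in all_ids:
                all_ids.append(sid)
    specimens = [
        SpecimenRecord(
            specimen_id=sid,
            species_label=species[sid],
            locus_status={
                locus: any(r[0] == sid for r in rows)
                for locus, rows in rows_by_locus.items()
            },
        )
        for sid in all_ids
    ]
    loci = {
        locus: LocusAlignment(locus_name=locus, rows=rows)
        for locus, rows in rows_by_locus.items()
    }
    return MultiLocusDataset(specimens=specimens, loci=loci)


@pytest.fixture(scope="session")
def preset_dataset():
    """Study-design synthetic dataset with default ILS sharing."""
    return generate(paper_preset())


@pytest.fixture(scope="session")
def clean_dataset():
    """Study-design dataset without ILS: every nearest neighbour conspecific."""
    cfg = paper_preset()
    cfg.ils_share_prob = 0.0
    return generate(cfg)
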