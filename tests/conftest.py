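import numpy as np
import pandas as pd
import pytest

from ticklink.profile_io import COLUMNS


def make_table(rows):
    """Build an annotation table from dicts of non-default fields."""
    base = {
        "feature_id": "f1",
        "sample_id": "S1",
        "hits": 1,
        "evalue": 1e-10,
        "identity_pct": 95.0,
        "aln_len": 50,
        "domain": "Bacteria",
        "phylum": "P1",
        "class": "C1",
        "order": "O1",
        "family": "F1",
        "genus": "G1",
        "func_l1": "L1",
        "func_l2": "L2",
        "func_l3": "L3",
        "func_l4": "1.1.1.1",
        "subject_id": "s1",
    }
    full = []
    for i, row in enumerate(rows):
        rec = dict(base)
        rec["feature_id"] = f"f{i + 1}"
        rec.update(row)
        full.append(rec)
    df = pd.DataFrame(full, columns=COLUMNS)
    df["hits"] = df["hits"].astype("int64")
    df["aln_len"] = df["aln_len"].astype("int64")
    return df


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_read(seq, quals, read_id="r1"):
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    rec = SeqRecord(Seq(seq), id=read_id, description="")
    if isinstance(quals, int):
        quals = [quals] * len(seq)
    rec.letter_annotations["phred_quality"] = list(quals)
    return rec
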