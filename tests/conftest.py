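"""Shared fixtures: the bundled six-specimen annotation set and the
published genome-organization values they must reproduce, plus a cached
synthetic bundle for the pipeline-level tests."""

from importlib import resources

import pytest

from dendromito.genome_model import read_annotation_table
from dendromito.organization import compute_junctions
from dendromito.synthetic_data import paper_shaped_preset, simulate_bundle

#: published signed junction lengths (spacer > 0, overlap < 0) for the six
#: newly sequenced specimens, columns LY04 LY08 SM12 SM22 YN05 YN11
PUBLISHED_JUNCTIONS = {
    "trnM-trnI": (3, 4, 3, 3, 1, 1),
    "trnI-trnQ": (-3, -3, -3, -3, -3, -3),
    "trnQ-nad2": (54, 54, 56, 54, 55, 55),
    "nad2-trnW": (-2, -2, -1, -1, -2, -2),
    "trnW-trnC": (-8, -8, -8, -8, -8, -8),
    "trnC-trnY": (0, 0, 0, 0, 1, 1),
    "trnY-cox1": (32, 32, 40, 41, 28, 28),
    "cox2-trnK": (0, 0, 0, 0, 1, 1),
    "trnK-trnD": (3, 3, 0, 0, 1, 1),
    "atp8-atp6": (-7, -7, -7, -7, -7, -7),
    "atp6-cox3": (12, 12, 6, 8, 15, 15),
    "cox3-trnG": (2, 2, 2, 2, 2, 2),
    "nad3-trnA": (4, 4, 2, 2, 0, 0),
    "trnA-trnR": (13, 13, 18, 18, 9, 9),
    "trnR-trnN": (1, 1, 21, 21, 5, 5),
    "trnN-trnS(AGN)": (16, 16, 14, 7, 25, 25),
    "trnS(AGN)-trnE": (-1, -1, -1, -1, -1, -1),
    "trnE-trnF": (12, 12, 13, 13, 8, 8),
    "trnF-nad5": (3, 3, 4, 4, 4, 4),
    "nad4-nad4l": (38, 38, 34, 32, 31, 31),
    "nad4l-trnT": (7, 7, 4, 4, 4, 4),
    "trnP-nad6": (8, 8, 8, 8, 8, 8),
    "nad6-cob": (4, 4, 3, 3, 5, 5),
    "cob-trnS(UCN)": (3, 3, -2, -2, 3, 3),
    "trnS(UCN)-nad1": (-1, -1, -1, -1, -1, -1),
    "nad1-trnL(CUN)": (1, 1, 1, 1, 1, 1),
}
JUNCTION_COLUMNS = ("LY04", "LY08", "SM12", "SM22", "YN05", "YN11")

#: published whole-genome lengths per representative specimen
PUBLISHED_LENGTHS = {"LY04": 15417, "YN05": 15381, "SM12": 15377}

#: the eight tRNAs encoded on the minority strand
MINORITY_STRAND_TRNAS = frozenset(
    ("trnQ", "trnC", "trnY", "trnF", "trnH", "trnP", "trnL(CUN)", "trnV")
)


@pytest.fixture(scope="session")
def table_records():
    with resources.as_file(
        resources.files("dendromito.data") / "dendrolimus_annotations.tsv"
    ) as path:
        return {rec.id: rec for rec in read_annotation_table(path)}


@pytest.fixture(scope="session")
def ledgers(table_records):
    return {
        rid: compute_junctions(rec) for rid, rec in table_records.items()
    }


@pytest.fixture(scope="session")
def preset_bundle():
    """One simulated 14-specimen data set (fixed seed), shared across
    pipeline-level tests."""
    return simulate_bundle(paper_shaped_preset(seed=1))
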