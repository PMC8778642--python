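"""Shared fixtures: a small deterministic study with hand-checkable structure.

The "split fixture" is an 8-organism x 12-family count table built so that
every expected contrast outcome can be enumerated by hand / brute force:

* organisms o1..o4 vs o5..o8 form the main split; three labels (pathogen,
  living_in_water, associated_with_animals) share the o5..o8 extent, so three
  configured pairs repeat the same 4-vs-4 comparison and drive recurrence;
* families F01..F11 separate the main split completely with strictly
  increasing median differences (10, 20, ..., 110), all values tie-free, so
  the exact two-sided rank-sum p is 2/70 for each;
* family F12 separates only the commensal-vs-mutualist split, contributing
  recurrence 1;
* with max_k = 10, F01 (the smallest difference) is crowded out of every
  top-ten list, so expected recurrences are F01: 0, F02..F11: 3, F12: 1.
"""

import pandas as pd
import pytest

from adaptasome import EcologyTable, FamilyCountMatrix, SelectionConfig

SPLIT_ORGANISMS = [f"o{i}" for i in range(1, 9)]
LOW_ORGS = SPLIT_ORGANISMS[:4]  # o1..o4
HIGH_ORGS = SPLIT_ORGANISMS[4:]  # o5..o8

SPLIT_PAIRS = (
    ("saprotroph", "pathogen"),
    ("saprotroph", "living_in_water"),
    ("saprotroph", "associated_with_animals"),
    ("commensal", "mutualist"),
)


def _split_family_key(j: int) -> tuple[str, str]:
    db = ("MEROPS", "CAZY", "TCDB")[(j - 1) // 4]
    return (db, f"F{j:02d}")


@pytest.fixture(scope="session")
def split_matrix() -> FamilyCountMatrix:
    cols = {}
    for j in range(1, 12):  # F01..F11: main-split separators, diff = 10j
        cols[_split_family_key(j)] = [0, 1, 2, 3] + [10 * j + d for d in range(4)]
    # F12 separates {o1,o2,o5,o6} (commensal) from {o3,o4,o7,o8} (mutualist)
    cols[_split_family_key(12)] = [50, 51, 0, 1, 52, 53, 2, 3]
    data = pd.DataFrame(cols, index=pd.Index(SPLIT_ORGANISMS, name="organism"))
    data.columns = pd.MultiIndex.from_tuples(data.columns, names=["database", "family"])
    return FamilyCountMatrix(data)


@pytest.fixture(scope="session")
def split_ecology() -> EcologyTable:
    entries = {}
    for org in SPLIT_ORGANISMS:
        labels = set()
        if org in LOW_ORGS:
            labels.add("saprotroph")
        else:
            labels |= {"pathogen", "living_in_water", "associated_with_animals"}
        labels.add("commensal" if org in {"o1", "o2", "o5", "o6"} else "mutualist")
        entries[org] = frozenset(labels)
    return EcologyTable(entries=entries)


@pytest.fixture(scope="session")
def split_config() -> SelectionConfig:
    # uncorrected gating: the hand enumeration uses the plain p < alpha rule
    return SelectionConfig(pairs=SPLIT_PAIRS, correction=None)
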