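import numpy as np
import pandas as pd
import pytest

from repsig.repertoire import CohortSample, Repertoire


@pytest.fixture
def toy_repertoire() -> Repertoire:
    """Three clonotypes with counts 8/1/1 -> frequencies 0.8/0.1/0.1."""
    return Repertoire.from_counts(
        "toy",
        ["CASSLGF", "CASSQEF", "CASSYNF"],
        ["TRBV5-1", "TRBV7-2", "TRBV19"],
        ["TRBJ2-7", "TRBJ1-1", "TRBJ2-3"],
        [8, 1, 1],
    )


@pytest.fixture
def uniform_repertoire():
    def make(n: int, sample_id: str = "uniform") -> Repertoire:
        cdr3 = [f"C{_aa_word(i)}F" for i in range(n)]
        return Repertoire.from_counts(
            sample_id, cdr3, ["TRBV19"] * n, ["TRBJ2-7"] * n, [5] * n
        )

    return make


_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _aa_word(i: int, width: int = 5) -> str:
    chars = []
    for _ in range(width):
        chars.append(_AA20[i % 20])
        i //= 20
    return "".join(chars)


def make_sample(
    sample_id: str,
    group: str,
    keyed_counts: dict,
    label_set=frozenset({"control", "previvor", "survivor", "negative", "positive"}),
) -> CohortSample:
    """Build a cohort sample from {(cdr3, v, j): count} or {cdr3: count}."""
    rows = []
    for key, count in keyed_counts.items():
        if isinstance(key, tuple):
            cdr3, v, j = key
        else:
            cdr3, v, j = key, "TRBV19", "TRBJ2-7"
        rows.append({"cdr3_aa": cdr3, "v_call": v, "j_call": j, "templates": count})
    rep = Repertoire(sample_id, pd.DataFrame(rows))
    return CohortSample(repertoire=rep, group=group, label_set=label_set)


@pytest.fixture
def aa_word():
    return _aa_word
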