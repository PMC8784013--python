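"""Genotype model and GENEPOP / tabular round trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msatpop.genotype_io import (
    MISSING,
    GenepopDialect,
    GenotypeMatrix,
    GenotypeParseError,
    TableSchema,
    read_genepop,
    read_table,
    table_schema_for,
    write_genepop,
    write_table,
)
from conftest import make_matrix

GENEPOP_TINY = """title line
locA
POP
a1 , 003003
a2 , 000000
POP
b1 , 003004
b2 , 004004
"""


def test_read_genepop_parses_calls_and_missing(tmp_path):
    path = tmp_path / "tiny.gen"
    path.write_text(GENEPOP_TINY)
    G = read_genepop(path, GenepopDialect(digits=3), grouping_name="pop")
    assert G.n_individuals == 4 and G.n_loci == 1
    assert tuple(G.alleles[0, 0]) == (3, 3)
    assert tuple(G.alleles[1, 0]) == (MISSING, MISSING)
    assert tuple(G.alleles[2, 0]) == (3, 4)
    assert G.missing_mask.sum() == 1
    assert len(G.classes("pop")) == 2


def test_read_genepop_errors(tmp_path):
    bad = tmp_path / "bad.gen"
    bad.write_text("t\nlocA\nPOP\na1 , 00300\n")
    with pytest.raises(GenotypeParseError, match="line|token|digits"):
        read_genepop(bad)
    dup = tmp_path / "dup.gen"
    dup.write_text("t\nlocA\nPOP\na1 , 003003\na1 , 003003\n")
    with pytest.raises(GenotypeParseError, match="duplicate"):
        read_genepop(dup)


def test_half_call_coerced_to_missing(tmp_path):
    path = tmp_path / "half.gen"
    path.write_text("t\nlocA\nPOP\na1 , 003000\n")
    G = read_genepop(path)
    assert G.missing_mask.all()


def test_write_genepop_tokens(tmp_path):
    G = make_matrix([[(150, 154)], [None]], groups=["x", "x"])
    path = tmp_path / "out.gen"
    write_genepop(G, path, "pop")
    lines = path.read_text().splitlines()
    assert lines[-2].endswith("150154")
    assert lines[-1].endswith("000000")


def test_write_genepop_width_overflow(tmp_path):
    G = make_matrix([[(1500, 4)]], groups=["x"])
    with pytest.raises(ValueError, match="remap"):
        write_genepop(G, tmp_path / "o.gen", "pop")
    legend = write_genepop(G, tmp_path / "o.gen", "pop", remap=True)
    assert legend["L1"] == {4: 1, 1500: 2}


def test_genepop_round_trip(tmp_path):
    G = make_matrix(
        [[(100, 102), (104, 104)], [None, (106, 108)], [(102, 102), None]],
        groups=["a", "a", "b"],
    )
    path = tmp_path / "rt.gen"
    write_genepop(G, path, "pop")
    back = read_genepop(path, grouping_name="pop", pop_names=["a", "b"])
    assert back == G


def test_table_round_trip_carries_both_groupings(tmp_path):
    G = make_matrix([[(150, 154)], [(150, 150)]], groups=["Albino", "Pearl grey"],
                    grouping_name="phenotype")
    G.set_grouping("zone", {"i1": "Atakora", "i2": "Dry Savannah"})
    path = tmp_path / "rt.csv"
    write_table(G, path)
    back = read_table(path, table_schema_for(G))
    assert back == G


def test_read_table_missing_and_errors(tmp_path):
    path = tmp_path / "g.csv"
    path.write_text("id,phenotype,zone,L1,L2\nind1,Albino,Atakora,150/154,\n")
    schema = TableSchema(grouping_cols={"phenotype": "phenotype", "zone": "zone"})
    G = read_table(path, schema)
    assert tuple(G.alleles[0, 0]) == (150, 154)
    assert G.missing_mask[0, 1]
    assert G.groupings["zone"]["ind1"] == "Atakora"
    bad = tmp_path / "bad.csv"
    bad.write_text("id,L1\nind1,xx/150\n")
    with pytest.raises(GenotypeParseError, match="non-integer"):
        read_table(bad, TableSchema())


def test_grouping_must_cover_all_individuals():
    with pytest.raises(ValueError, match="lacks a class"):
        make_matrix([[(1, 2)], [(1, 1)]], groups=None).set_grouping("g", {"i1": "x"})


@st.composite
def genotype_matrices(draw):
    n = draw(st.integers(2, 6))
    L = draw(st.integers(1, 4))
    calls = []
    for _ in range(n):
        row = []
        for _ in range(L):
            if draw(st.booleans()) and draw(st.integers(0, 9)) == 0:
                row.append(None)
            else:
                a = draw(st.integers(1, 999))
                b = draw(st.integers(1, 999))
                row.append((a, b))
        calls.append(row)
    groups = [draw(st.sampled_from(["a", "b"])) for _ in range(n)]
    return make_matrix(calls, groups)


@given(genotype_matrices())
@settings(max_examples=40, deadline=None, derandomize=True)
def test_genepop_round_trip_property(tmp_path_factory, G):
    """read(write(G)) preserves every call and never drops individuals."""
    path = tmp_path_factory.mktemp("rt") / "m.gen"
    write_genepop(G, path, "pop")
    classes = G.classes("pop")
    back = read_genepop(path, grouping_name="pop", pop_names=classes)
    assert back.n_individuals == G.n_individuals
    # writer groups individuals by class; compare per-id calls
    order = [back.individual_ids.index(i) for i in G.individual_ids]
    assert np.array_equal(back.alleles[order], G.alleles)
    assert back.groupings["pop"] == G.groupings["pop"]
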