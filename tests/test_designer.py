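import pytest

from haloterm import catalog
from haloterm.core_io import NucleotideSequence
from haloterm.designer import (
    DesignError,
    DesignSpec,
    de_novo_design,
    mutate_stem,
    mutate_tract,
    set_loop,
    truncate_flanks,
)
from haloterm.features import extract_features
from haloterm.hairpin_fold import fold_hairpin
from haloterm.te_model import predict_te


def test_set_loop_shrinks_a04_loop():
    """Replacing the 10-nt loop of the weakest native part with the stable
    5-nt ATGAC loop refolds to a 5-nt loop on the same 8-bp stem."""
    out = set_loop(catalog.get("A04"), "ATGAC")
    h = fold_hairpin(out.seq)
    assert h.loops[0][1] == "ATGAC"
    assert h.n_H == 8


def test_set_loop_identity_and_validation():
    g01 = catalog.get("G01")
    same = set_loop(g01, "ATGAC")  # already the loop
    assert same.seq == g01.seq
    with pytest.raises(DesignError):
        set_loop(g01, "AT")  # loops below 3 nt are rejected
    with pytest.raises(DesignError):
        set_loop(NucleotideSequence("flat", "A" * 40), "ATGAC")


def test_set_loop_changes_only_the_loop_segment():
    g01 = catalog.get("G01")
    before = fold_hairpin(g01.seq)
    after = fold_hairpin(set_loop(g01, "GTTA").seq)
    assert after.loops[0][1] == "GTTA"
    assert (after.stem5, after.stem3) == (before.stem5, before.stem3)
    assert (after.a_tract, after.u_tract) == (before.a_tract, before.u_tract)
    assert (after.five_tail, after.three_tail) == (before.five_tail, before.three_tail)


def test_truncate_flanks_g01_gives_printed_g04():
    out = truncate_flanks(catalog.get("G01"), 8, 8)
    assert out.seq == catalog.SEQUENCES["G04"][0]  # byte-exact published part


def test_truncate_flanks_identity_and_stem_protection():
    g01 = catalog.get("G01")
    assert truncate_flanks(g01, 0, 0).seq == g01.seq
    with pytest.raises(DesignError):
        truncate_flanks(g01, 16, 0)  # would cut past the 5' tail + A-tract


def test_mutate_tract_degrades_uscore():
    g01 = catalog.get("G01")
    degraded = mutate_tract(g01, "u", "CCAC")
    assert extract_features(degraded).uscore < extract_features(g01).uscore


def test_mutate_tract_validation():
    g01 = catalog.get("G01")
    with pytest.raises(DesignError):
        mutate_tract(g01, "u", "CC")  # length mismatch
    with pytest.raises(DesignError):
        mutate_tract(g01, "x", "CCAC")


def test_mutate_stem_g05_like_drops_predicted_te():
    """A 4-bp moderate-GC stem (the G05 design move) lowers the predicted TE
    relative to the 8-bp GC-rich G01 stem."""
    g01 = catalog.get("G01")
    weak = mutate_stem(g01, 4, 0.75, seed=7)
    f = extract_features(weak)
    assert f.n_H == 4
    assert predict_te(f) < predict_te(extract_features(g01))


def test_mutate_stem_is_deterministic():
    g01 = catalog.get("G01")
    a = mutate_stem(g01, 8, 0.875, seed=5)
    b = mutate_stem(g01, 8, 0.875, seed=5)
    assert a.seq == b.seq


@pytest.mark.parametrize("a_len,u_len,stem_len,gc,loop", [
    (10, 10, 8, 1.0, "GTTA"),   # the de novo D01 blueprint
    (8, 8, 8, 0.875, "ATGAC"),
    (10, 10, 6, 1.0, "TTTC"),
])
def test_de_novo_design_round_trips_spec(a_len, u_len, stem_len, gc, loop):
    spec = DesignSpec(a_len=a_len, u_len=u_len, stem_len=stem_len,
                      stem_gc=gc, loop_seq=loop, seed=2)
    rec = de_novo_design(spec)
    f = extract_features(rec)
    assert f.n_H == stem_len
    assert f.loop_sizes == (len(loop),)
    assert f.a_tract_len == a_len
    assert f.u_tract_len == u_len
    if gc == 1.0:
        h = fold_hairpin(rec.seq)
        assert set(h.stem5) <= {"G", "C"}


def test_de_novo_design_deterministic_and_validated():
    spec = DesignSpec(a_len=10, u_len=10, stem_len=8, stem_gc=1.0,
                      loop_seq="GTTA", seed=3)
    assert de_novo_design(spec).seq == de_novo_design(spec).seq
    with pytest.raises(DesignError):
        # an all-A:T 4-bp stem cannot survive as a hairpin
        de_novo_design(DesignSpec(a_len=6, u_len=6, stem_len=4, stem_gc=0.0,
                                  loop_seq="GTTA", seed=0))


def test_design_spec_validation():
    with pytest.raises(DesignError):
        DesignSpec(a_len=8, u_len=8, stem_len=3, stem_gc=1.0, loop_seq="GTTA")
    with pytest.raises(DesignError):
        DesignSpec(a_len=8, u_len=8, stem_len=8, stem_gc=1.0, loop_seq="GT")
    with pytest.raises(DesignError):
        DesignSpec(a_len=-1, u_len=8, stem_len=8, stem_gc=1.0, loop_seq="GTTA")
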