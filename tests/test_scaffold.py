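"""Construct assembly, folding backends and stem-loop parsing."""

import numpy as np
import pytest

import aptazyme as az
from aptazyme import errors
from aptazyme.scaffold import pair_table, recover_inserts


class TestAssemble:
    def test_length_bookkeeping(self, scaffold_fx):
        c = az.assemble("GUGA", "ACAA", scaffold_fx)
        assert len(c.full_sequence) == scaffold_fx.fixed_length + 8

    def test_native_loops_reconstruct_literature_sequence(self, scaffold_fx):
        c = az.assemble(scaffold_fx.native_loop1, scaffold_fx.native_loop2,
                        scaffold_fx)
        assert c.full_sequence == scaffold_fx.native_full_sequence

    def test_t_mapped_and_lowercase_uppercased(self, scaffold_fx):
        c = az.assemble("gtga", "acaa", scaffold_fx)
        assert c.loop1_insert == "GUGA"

    @pytest.mark.parametrize("l1,l2,err", [
        ("GXGA", "ACAA", errors.InvalidAlphabet),
        ("", "ACAA", errors.InvalidLoop),
        ("GUGA", "", errors.InvalidLoop),
    ])
    def test_rejects_bad_inserts(self, scaffold_fx, l1, l2, err):
        with pytest.raises(err):
            az.assemble(l1, l2, scaffold_fx)

    def test_insert_round_trip_random(self, scaffold_fx):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n1, n2 = rng.integers(3, 14, size=2)
            l1 = "".join(rng.choice(list("ACGU"), n1))
            l2 = "".join(rng.choice(list("ACGU"), n2))
            c = az.assemble(l1, l2, scaffold_fx)
            assert recover_inserts(c, scaffold_fx) == (l1, l2)

    def test_stem_arms_are_reverse_complements(self, scaffold_fx):
        s = scaffold_fx.segments
        assert az.scaffold.reverse_complement(s["stem1_5arm"]) == s["stem1_3arm"]
        assert az.scaffold.reverse_complement(s["stem2_5arm"]) == s["stem2_3arm"]


class TestFold:
    @pytest.mark.parametrize("backend", ["vienna", "nussinov"])
    def test_simple_hairpin(self, backend):
        st = az.fold("GGGGAAAACCCC", backend)
        assert st.dot_bracket == "((((....))))"

    @pytest.mark.parametrize("backend", ["vienna", "nussinov"])
    def test_unpairable_sequence_is_open(self, backend):
        assert az.fold("AAAAAAAA", backend).dot_bracket == "........"

    @pytest.mark.parametrize("backend", ["vienna", "nussinov"])
    def test_deterministic(self, backend):
        seq = "GCGCUUCGGCAAAGGCGC"
        assert az.fold(seq, backend).dot_bracket == az.fold(seq, backend).dot_bracket

    def test_too_long_rejected(self):
        with pytest.raises(errors.InputTooLong):
            az.fold("A" * 301)

    def test_unknown_backend(self):
        with pytest.raises(errors.BackendError):
            az.fold("ACGU" * 4, backend="mfold")

    def test_native_scaffold_stems_fully_paired(self, scaffold_fx):
        c = az.assemble(scaffold_fx.native_loop1, scaffold_fx.native_loop2,
                        scaffold_fx)
        st = az.fold(c.full_sequence)
        sl1, sl2, reason = az.parse_stemloops(st, scaffold_fx, 7, 4)
        assert reason == ""
        assert sl1.stem_len >= scaffold_fx.default_stem1_len
        assert sl2.stem_len >= scaffold_fx.default_stem2_len


class TestParseStemloops:
    def test_plain_tetraloop_no_extension(self, scaffold_fx):
        p = az.analyze("GAAA", "GUGA", scaffold_fx)
        assert not p.misfolded
        assert p.sl1.stem_len == scaffold_fx.default_stem1_len
        assert p.sl1.loop_len == 4 and p.sl1.loop_sequence == "GAAA"

    def test_pairing_loop_ends_extend_stem(self, scaffold_fx):
        # first two / last two inserted bases are complementary: the folder
        # credits them to the stem, shortening the actual loop
        p = az.analyze("GGGAAACCC", "GUGA", scaffold_fx)
        assert not p.misfolded
        assert p.sl1.stem_len > scaffold_fx.default_stem1_len
        ext = p.sl1.stem_len - scaffold_fx.default_stem1_len
        assert p.sl1.loop_len == 9 - 2 * ext

    def test_long_loop_grows_branch_stem(self, scaffold_fx):
        # 13-nt insert carrying an internal hairpin
        p = az.analyze("AAGGGCGAAAGCC", "GUGA", scaffold_fx)
        assert not p.misfolded
        assert p.sl1.branch_stems
        n_paired = sum(p.sl1.paired_flags)
        n_bp = sum(len(o) for o, _ in p.sl1.branch_stems)
        assert n_paired == 2 * n_bp
        assert n_paired % 2 == 0

    def test_misfold_flag_instead_of_raise(self, scaffold_fx):
        # the maximum-pairing test folder shifts the designed stem register
        c = az.assemble(scaffold_fx.native_loop1, scaffold_fx.native_loop2,
                        scaffold_fx)
        st = az.fold(c.full_sequence, backend="nussinov")
        sl1, sl2, reason = az.parse_stemloops(st, scaffold_fx, 7, 4)
        assert reason != "" and sl1 is None and sl2 is None

    def test_paired_flag_count_always_even(self, scaffold_fx):
        rng = np.random.default_rng(1)
        for _ in range(60):
            n1, n2 = rng.integers(5, 14, size=2)
            p = az.analyze("".join(rng.choice(list("ACGU"), n1)),
                           "".join(rng.choice(list("ACGU"), n2)), scaffold_fx)
            if not p.misfolded:
                assert sum(p.sl1.paired_flags) % 2 == 0
                assert sum(p.sl2.paired_flags) % 2 == 0


class TestStructureKey:
    def test_deterministic_and_ordered(self, scaffold_fx):
        p = az.analyze("GAAA", "GUGA", scaffold_fx)
        k1 = az.structure_key(p.sl1, p.sl2)
        assert k1 == az.structure_key(p.sl1, p.sl2)
        swapped = az.StructureKey(k1.stem2_len, k1.stem1_len, k1.loop2_len,
                                  k1.loop1_len, k1.branch2, k1.branch1)
        assert swapped != k1

    def test_keys_partition_dataset(self, small_data):
        keys = small_data["keys"]
        assert all(k is not None for k in keys)
        assert len(keys) == len(small_data["parsed"])

    def test_n4n4_slice_key_conservation(self, scaffold_fx):
        """N4 loops share the plain key unless the fold credits loop bases to
        the stem; either way stem growth exactly accounts for loop shrinkage."""
        from collections import Counter
        rng = np.random.default_rng(2)
        keys = []
        for _ in range(60):
            l1 = "".join(rng.choice(list("ACGU"), 4))
            l2 = "".join(rng.choice(list("ACGU"), 4))
            p = az.analyze(l1, l2, scaffold_fx)
            if p.misfolded:
                continue
            k = p.key
            assert 2 * (k.stem1_len - 6) + k.loop1_len == 4
            assert 2 * (k.stem2_len - 4) + k.loop2_len == 4
            keys.append(k)
        modal_key, _ = Counter(keys).most_common(1)[0]
        assert modal_key == az.StructureKey(6, 4, 4, 4, False, False)


def test_pair_table_round_trip():
    pt = pair_table("((..)).")
    assert pt[0] == 5 and pt[1] == 4 and pt[2] == -1 and pt[6] == -1
    with pytest.raises(ValueError):
        pair_table("((.)")
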