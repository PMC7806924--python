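import numpy as np
import pytest
from oracles import gene_drop_kinship

from pedherit import (
    Individual,
    Pedigree,
    PedigreeError,
    Sex,
    compute_kinship,
    read_pedigree,
    relative_pairs,
    write_pedigree,
)


def _write(tmp_path, lines, name="ped.txt"):
    path = tmp_path / name
    path.write_text("\n".join(lines) + "\n")
    return path


class TestReadPedigree:
    def test_minimal_trio(self, tmp_path):
        path = _write(tmp_path, [
            "FAM1 dad 0 0 1",
            "FAM1 mom 0 0 2",
            "FAM1 kid dad mom 2",
        ])
        ped = read_pedigree(path)
        assert len(ped) == 3
        assert set(ped.founders) == {"dad", "mom"}
        assert ped.nonfounders == ["kid"]
        assert ped["kid"].sex == Sex.FEMALE

    def test_child_listed_before_parents_is_reordered(self, tmp_path):
        shuffled = read_pedigree(_write(tmp_path, [
            "FAM1 kid dad mom 2",
            "FAM1 dad 0 0 1",
            "FAM1 mom 0 0 2",
        ]))
        for iid in ("dad", "mom"):
            assert shuffled.index[iid] < shuffled.index["kid"]

    def test_unresolvable_father_names_the_id(self, tmp_path):
        path = _write(tmp_path, [
            "FAM1 mom 0 0 2",
            "FAM1 kid ghostdad mom 2",
            "FAM1 ghostdad2 0 0 1",
        ])
        with pytest.raises(PedigreeError, match="ghostdad"):
            read_pedigree(path)

    def test_parent_in_other_family_rejected(self, tmp_path):
        path = _write(tmp_path, [
            "FAM1 dad 0 0 1",
            "FAM2 mom 0 0 2",
            "FAM2 kid dad mom 1",
        ])
        with pytest.raises(PedigreeError, match="dad"):
            read_pedigree(path)

    def test_duplicate_id_rejected(self, tmp_path):
        path = _write(tmp_path, ["F a 0 0 1", "F a 0 0 2"])
        with pytest.raises(PedigreeError, match="duplicate.*'a'"):
            read_pedigree(path)

    def test_cycle_rejected(self):
        with pytest.raises(PedigreeError, match="cycle"):
            Pedigree([
                Individual("x", "F", "y", "m", Sex.MALE),
                Individual("y", "F", "x", "m", Sex.MALE),
                Individual("m", "F", None, None, Sex.FEMALE),
            ])

    def test_single_parent_rejected_unless_padded(self):
        rows = [
            Individual("mom", "F", None, None, Sex.FEMALE),
            Individual("kid", "F", None, "mom", Sex.MALE),
        ]
        with pytest.raises(PedigreeError, match="single parent"):
            Pedigree(rows)
        ped = Pedigree(rows, pad_single_parent=True)
        assert len(ped) == 3
        assert not ped["kid"].is_founder

    def test_roundtrip_through_fam_dialect(self, trio, tmp_path):
        path = tmp_path / "out.fam"
        write_pedigree(trio, path)
        back = read_pedigree(path, dialect="plink_fam")
        assert back.ids == trio.ids
        assert back["kid"].father_id == "dad"


class TestKinship:
    def test_textbook_identities(self, two_generation):
        kin = compute_kinship(two_generation)
        assert kin.phi("f1", "a") == 0.25        # parent-offspring
        assert kin.phi("a", "b") == 0.25         # full sibs
        assert kin.phi("a", "c") == 0.125        # half sibs
        assert kin.phi("d1", "g") == 0.0625      # first cousins
        assert kin.phi("b", "d1") == 0.125       # avuncular
        assert kin.phi("f1", "m1") == 0.0        # unrelated founders
        assert kin.phi("a", "a") == 0.5          # non-inbred diagonal

    def test_full_sib_mating_inbred_diagonal(self):
        ped = Pedigree([
            Individual("f", "F", None, None, Sex.MALE),
            Individual("m", "F", None, None, Sex.FEMALE),
            Individual("s1", "F", "f", "m", Sex.MALE),
            Individual("s2", "F", "f", "m", Sex.FEMALE),
            Individual("inb", "F", "s1", "s2", Sex.MALE),
        ])
        kin = compute_kinship(ped)
        assert kin.phi("inb", "inb") == pytest.approx(0.625)

    def test_input_order_invariance(self, two_generation):
        kin = compute_kinship(two_generation)
        reordered = Pedigree(list(reversed(two_generation.individuals)))
        kin2 = compute_kinship(reordered)
        for i in two_generation.ids:
            for j in two_generation.ids:
                assert kin.phi(i, j) == kin2.phi(i, j)

    def test_blocks_are_positive_semidefinite(self, sib_quads, two_generation):
        for ped in (sib_quads, two_generation):
            kin = compute_kinship(ped)
            for block in kin.family_blocks():
                K = 2 * kin.values[np.ix_(block, block)]
                assert np.linalg.eigvalsh(K).min() >= -1e-8

    def test_agrees_with_gene_dropping(self, two_generation):
        """Recursive kinship matches a 60k-drop Monte-Carlo estimate."""
        kin = compute_kinship(two_generation)
        rng = np.random.default_rng(42)
        phi_mc = gene_drop_kinship(two_generation, 60_000, rng)
        order = [two_generation.index[i] for i in kin.ids]
        assert np.abs(kin.values - phi_mc[np.ix_(order, order)]).max() < 0.005

    def test_long_format_export(self, trio):
        kin = compute_kinship(trio)
        long = kin.to_long()
        assert set(long.columns) == {"id1", "id2", "phi"}
        assert len(long) == 2  # two parent-offspring pairs; parents unrelated
        assert (long["phi"] == 0.25).all()


class TestRelativePairs:
    def test_trio_counts(self, trio):
        table = relative_pairs(trio).set_index("pair_class")["count"]
        assert table["phi=0.25 (parent-offspring / full sibs)"] == 2
        assert table["total related"] == 2

    def test_two_unrelated_trios_double_without_cross_pairs(self, trio):
        rows = list(trio.individuals) + [
            Individual("dad2", "FAM2", None, None, Sex.MALE),
            Individual("mom2", "FAM2", None, None, Sex.FEMALE),
            Individual("kid2", "FAM2", "dad2", "mom2", Sex.MALE),
        ]
        table = relative_pairs(Pedigree(rows)).set_index("pair_class")["count"]
        assert table["phi=0.25 (parent-offspring / full sibs)"] == 4
        assert table["total related"] == 4

    def test_subset_restriction(self, two_generation):
        kin = compute_kinship(two_generation)
        table = relative_pairs(
            two_generation, kin, ids=["a", "b", "c"]
        ).set_index("pair_class")["count"]
        assert table["phi=0.25 (parent-offspring / full sibs)"] == 1  # a-b
        assert table["phi=0.125 (half sibs / avuncular / grandparental)"] == 2
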