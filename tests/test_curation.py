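"""Curation rules, MaxMin diversity selection and class balancing."""

import numpy as np
import pytest

from consvote import (CompoundRecord, Outcome, balance, canonical_smiles,
                      curate, gen_toy_smiles, maxmin_select, read_assay_csv,
                      write_smi)
from consvote.curation import CurationWarning, read_smi

from helpers_oracles import greedy_maxmin


def rec(cid, smiles, outcome):
    return CompoundRecord(cid, smiles, Outcome(outcome))


class TestCurate:
    def test_inconclusive_removed(self):
        records = [rec("a", "CCO", "active"),
                   rec("b", "CCN", "inconclusive")]
        kept, log = curate(records)
        assert [r.compound_id for r in kept] == ["a"]
        assert log.n_inconclusive == 1 and log.n_output == 1

    def test_empty_input_gives_zero_log(self):
        kept, log = curate([])
        assert kept == [] and log.n_input == log.n_output == 0

    def test_unparseable_and_empty_smiles_counted_together(self):
        records = [rec("a", "", "active"),
                   rec("b", "not_a_smiles((", "active"),
                   rec("c", "c1ccccc1", "inactive")]
        kept, log = curate(records)
        assert log.n_no_smiles == 2 and [r.compound_id for r in kept] == ["c"]

    def test_duplicate_structures_all_removed(self):
        # benzene written two ways plus three unique structures
        records = [rec("a", "c1ccccc1", "active"),
                   rec("b", "C1=CC=CC=C1", "inactive"),
                   rec("c", "CCO", "active"),
                   rec("d", "CCN", "inactive"),
                   rec("e", "CCC", "active")]
        kept, log = curate(records)
        assert len(kept) == 3 and log.n_duplicates == 2
        assert {r.compound_id for r in kept} == {"c", "d", "e"}

    def test_concordant_duplicates_kept_once_when_enabled(self):
        records = [rec("a", "c1ccccc1", "active"),
                   rec("b", "C1=CC=CC=C1", "active"),
                   rec("c", "CCO", "inactive")]
        kept, log = curate(records, keep_concordant_duplicates=True)
        assert [r.compound_id for r in kept] == ["a", "c"]
        assert log.n_duplicates == 1
        # discordant pairs are still removed entirely
        records[1] = rec("b", "C1=CC=CC=C1", "inactive")
        kept, log = curate(records, keep_concordant_duplicates=True)
        assert [r.compound_id for r in kept] == ["c"]

    def test_all_eliminated_warns(self):
        with pytest.warns(CurationWarning):
            kept, _ = curate([rec("a", "", "active")])
        assert kept == []

    def test_idempotent_on_toy_fixtures(self):
        records = gen_toy_smiles(40, seed=3)
        once, log1 = curate(records)
        twice, log2 = curate(once)
        assert once == twice
        assert log2.n_no_smiles == log2.n_inconclusive == 0
        assert log2.n_duplicates == 0

    def test_log_counts_reconcile(self):
        records = gen_toy_smiles(60, seed=9)
        _, log = curate(records)
        assert (log.n_output == log.n_input - log.n_no_smiles
                - log.n_inconclusive - log.n_duplicates)


class TestMaxMin:
    def test_k_equals_pool_returns_all(self, rng):
        pool = list(rng.integers(0, 2, size=(6, 16)))
        sel = maxmin_select(pool, k=6, seed=0)
        assert sorted(sel) == list(range(6))

    def test_farthest_point_forced(self):
        a = np.array([1, 1, 0, 0], dtype=bool)
        b = a.copy()                      # identical to a
        c = np.array([0, 0, 1, 1], dtype=bool)  # disjoint from both
        sel = maxmin_select([a, b, c], k=2, seed=11)
        assert 2 in sel                    # c always selected
        assert not {0, 1} <= set(sel)      # never both near-duplicates

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_exhaustive_greedy_oracle(self, seed):
        gen = np.random.default_rng(seed)
        pool = list(gen.integers(0, 2, size=(8, 32)).astype(bool))
        sel = maxmin_select(pool, k=4, seed=seed)
        assert sel == greedy_maxmin(pool, k=4, first=sel[0])

    def test_step1_pair_attains_max_distance_from_first_pick(self, rng):
        from consvote.curation import tanimoto_distance_matrix
        pool = rng.integers(0, 2, size=(10, 24)).astype(bool)
        sel = maxmin_select(list(pool), k=2, seed=5)
        dist = tanimoto_distance_matrix(pool)
        assert dist[sel[0], sel[1]] == pytest.approx(dist[sel[0]].max())

    def test_permutation_invariance_given_same_first_pick(self, rng):
        # fingerprints made distinct so selections map 1:1 through the perm
        pool = list(rng.integers(0, 2, size=(9, 40)).astype(bool))
        sel = maxmin_select(pool, k=5, seed=2, first=3)
        perm = list(np.random.default_rng(0).permutation(9))
        permuted_pool = [pool[i] for i in perm]
        sel_perm = maxmin_select(permuted_pool, k=5, seed=99,
                                 first=perm.index(3))
        assert {perm[i] for i in sel_perm} == set(sel)

    def test_argument_errors(self, rng):
        pool = list(rng.integers(0, 2, size=(3, 8)))
        with pytest.raises(ValueError):
            maxmin_select(pool, k=4, seed=0)
        with pytest.raises(ValueError):
            maxmin_select([], k=1, seed=0)

    def test_deterministic_given_seed(self, rng):
        pool = list(rng.integers(0, 2, size=(12, 16)))
        assert maxmin_select(pool, 6, seed=4) == maxmin_select(pool, 6, seed=4)


class TestBalance:
    def _records(self, n, outcome, prefix):
        smis = ["C" * (i + 1) + "O" for i in range(n)]
        return [rec(f"{prefix}{i}", s, outcome) for i, s in enumerate(smis)]

    def test_one_to_one_ratio(self, rng):
        actives = self._records(10, "active", "a")
        inactives = self._records(30, "inactive", "i")
        fps = list(rng.integers(0, 2, size=(30, 64)))
        out = balance(actives, inactives, seed=0, fingerprints=fps)
        assert len(out) == 20
        assert sum(r.outcome == Outcome.ACTIVE for r in out) == 10

    def test_equal_counts_all_kept(self):
        actives = self._records(10, "active", "a")
        inactives = self._records(10, "inactive", "i")
        out = balance(actives, inactives, seed=0,
                      fingerprints=[np.ones(8)] * 10)
        assert len(out) == 20

    def test_fewer_inactives_warns_and_keeps_all(self):
        actives = self._records(5, "active", "a")
        inactives = self._records(3, "inactive", "i")
        with pytest.warns(CurationWarning):
            out = balance(actives, inactives, seed=0)
        assert len(out) == 8

    def test_picks_match_greedy_oracle(self, rng):
        actives = self._records(5, "active", "a")
        inactives = self._records(12, "inactive", "i")
        # clustered pool: two tight clusters plus scattered points
        fps = np.zeros((12, 32), dtype=bool)
        fps[:6, :8] = rng.random((6, 8)) < 0.9
        fps[6:, 24:] = rng.random((6, 8)) < 0.9
        out = balance(actives, inactives, seed=1, fingerprints=list(fps))
        picked = sorted(int(r.compound_id[1:]) for r in out
                        if r.outcome == Outcome.INACTIVE)
        sel = maxmin_select(list(fps), k=5, seed=1)
        assert picked == sorted(greedy_maxmin(list(fps), k=5, first=sel[0]))

    def test_ecfp_computed_when_fingerprints_omitted(self):
        actives = self._records(2, "active", "a")
        inactives = self._records(4, "inactive", "i")
        out = balance(actives, inactives, seed=0)
        assert len(out) == 4


class TestIO:
    def test_assay_csv_roundtrip_with_aliases(self, tmp_path):
        csv = tmp_path / "assay.csv"
        csv.write_text(
            "PUBCHEM_CID,PUBCHEM_EXT_DATASOURCE_SMILES,"
            "PUBCHEM_ACTIVITY_OUTCOME\n"
            "1,CCO,Active\n2,CCN,Inactive\n3,CCC,Inconclusive\n")
        records = read_assay_csv(csv, source="aid777")
        assert [r.outcome.value for r in records] == [
            "active", "inactive", "inconclusive"]
        assert records[0].source == "aid777"

    def test_unknown_outcome_names_row(self, tmp_path):
        csv = tmp_path / "assay.csv"
        csv.write_text("compound_id,smiles,outcome\n1,CCO,banana\n")
        with pytest.raises(ValueError, match="row 2"):
            read_assay_csv(csv)

    def test_missing_column_is_explicit(self, tmp_path):
        csv = tmp_path / "assay.csv"
        csv.write_text("id_only\n1\n")
        with pytest.raises(ValueError, match="no column found"):
            read_assay_csv(csv)

    def test_smi_roundtrip(self, tmp_path):
        records = [rec("a", "CCO", "active"), rec("b", "c1ccccc1", "inactive")]
        path = tmp_path / "out.smi"
        write_smi(records, path)
        assert read_smi(path) == [("a", "CCO"), ("b", "c1ccccc1")]


def test_canonical_smiles_collapses_encodings():
    assert canonical_smiles("c1ccccc1") == canonical_smiles("C1=CC=CC=C1")
    assert canonical_smiles("") is None
    assert canonical_smiles("xx((") is None
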