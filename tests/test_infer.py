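"""OTU -> genome -> ortholog abundance transformation and its invariants."""

import numpy as np
import pandas as pd
import pytest

from koinfer.infer import assign_otus, floor_counts, infer_ko_abundance, passed_fraction
from koinfer.nnsearch import HitSet
from koinfer.refdb import GenomeRecord, ReferenceDatabase
from koinfer.synthetic import naive_ko_abundance
from koinfer.tables import KoAbundanceTable

from conftest import make_otu_table, random_seq


def _hit(otu, *genomes, identity=1.0):
    return HitSet(otu_id=otu, best_identity=identity, genome_ids=frozenset(genomes))


def _db(genome_defs: dict) -> ReferenceDatabase:
    """genome_defs: gid -> (rrna_copy_number, ko_copies)."""
    rng = np.random.default_rng(42)
    genomes = {}
    for gid, (rcopy, kcopies) in genome_defs.items():
        seq = random_seq(rng, 1500)
        genomes[gid] = GenomeRecord(gid, (seq,) * rcopy, kcopies)
    return ReferenceDatabase(genomes=genomes)


class TestAssignOtus:
    def test_single_hit_gets_full_abundance(self):
        otus = make_otu_table([[10.0]])
        table = assign_otus(otus, {"OTU1": _hit("OTU1", "g1")})
        assert table.df.loc["g1", "S1"] == 10.0

    def test_two_way_tie_splits_in_half(self):
        otus = make_otu_table([[10.0]])
        table = assign_otus(otus, {"OTU1": _hit("OTU1", "g1", "g2")})
        assert table.df.loc["g1", "S1"] == 5.0
        assert table.df.loc["g2", "S1"] == 5.0

    def test_two_otus_same_genome_add(self):
        otus = make_otu_table([[3.0], [7.0]])
        hits = {"OTU1": _hit("OTU1", "g1"), "OTU2": _hit("OTU2", "g1")}
        assert assign_otus(otus, hits).df.loc["g1", "S1"] == 10.0

    def test_conservation_of_column_sums(self, small_ref, exact_community):
        """Per-sample genome totals equal the passing-OTU abundance totals."""
        otus = exact_community.otu_table
        hits = exact_community.truth_hits
        table = assign_otus(otus, hits)
        np.testing.assert_allclose(
            table.matrix.sum(axis=0), otus.matrix.sum(axis=0), rtol=0, atol=1e-9
        )

    def test_unknown_hit_otu_rejected(self):
        otus = make_otu_table([[1.0]])
        with pytest.raises(ValueError):
            assign_otus(otus, {"ghost": _hit("ghost", "g1")})


class TestInferKoAbundance:
    def test_direct_formula_single_genome(self):
        # abundance 10, Rcopy 2, Kcopy 4 -> 10 * 4/2 = 20
        db = _db({"g1": (2, {"K00001": 4})})
        otus = make_otu_table([[10.0]])
        table = infer_ko_abundance(otus, {"OTU1": _hit("OTU1", "g1")}, db)
        assert table.df.loc["K00001", "S1"] == 20.0

    def test_tie_averages_genome_ratios(self):
        # abundance 12, m=2: g1 (R=1, K=1), g2 (R=3, K=6) -> 12*(1/1 + 6/3)/2 = 18
        db = _db({"g1": (1, {"K00009": 1}), "g2": (3, {"K00009": 6})})
        otus = make_otu_table([[12.0]])
        table = infer_ko_abundance(otus, {"OTU1": _hit("OTU1", "g1", "g2")}, db)
        assert table.df.loc["K00009", "S1"] == 18.0

    def test_all_zero_ko_absent_by_default_present_with_flag(self):
        db = _db({"g1": (1, {"K00001": 2, "K00002": 0})})
        db.genomes["g2"] = GenomeRecord(
            "g2", db.genomes["g1"].rrna_seqs, {"K00002": 5}
        )
        otus = make_otu_table([[4.0]])
        hits = {"OTU1": _hit("OTU1", "g1")}
        default = infer_ko_abundance(otus, hits, db)
        assert "K00002" not in default.df.index  # zero copies in the hit genome
        full = infer_ko_abundance(otus, hits, db, full_universe=True)
        assert full.df.loc["K00002", "S1"] == 0.0
        assert set(full.df.index) == set(db.ortholog_universe)

    def test_missing_genome_in_db_rejected(self):
        db = _db({"g1": (1, {"K00001": 1})})
        otus = make_otu_table([[1.0]])
        with pytest.raises(KeyError):
            infer_ko_abundance(otus, {"OTU1": _hit("OTU1", "gX")}, db)

    def test_dropped_otus_contribute_nothing(self):
        db = _db({"g1": (1, {"K00001": 1})})
        otus = make_otu_table([[5.0], [100.0]])
        table = infer_ko_abundance(otus, {"OTU1": _hit("OTU1", "g1")}, db)
        assert table.df.loc["K00001", "S1"] == 5.0

    def test_linearity_under_scaling(self, small_ref, exact_community):
        db, _ = small_ref
        otus = exact_community.otu_table
        hits = exact_community.truth_hits
        base = infer_ko_abundance(otus, hits, db)
        doubled = infer_ko_abundance(
            make_otu_table(otus.matrix * 2, otus.feature_ids, otus.sample_ids),
            hits, db,
        )
        np.testing.assert_allclose(
            doubled.matrix, base.matrix * 2, rtol=1e-12, atol=0
        )

    def test_matches_naive_oracle_on_random_communities(self):
        """Vectorized inference equals the triple-loop formula to 1e-9."""
        rng = np.random.default_rng(123)
        for _ in range(10):
            n_genomes = int(rng.integers(2, 12))
            n_kos = int(rng.integers(1, 60))
            n_otus = int(rng.integers(1, 30))
            n_samples = int(rng.integers(1, 5))
            ko_ids = [f"K{i:05d}" for i in range(n_kos)]
            db = _db({
                f"g{g}": (
                    int(rng.integers(1, 8)),
                    {k: int(c) for k, c in zip(ko_ids, rng.integers(0, 6, n_kos)) if c},
                )
                for g in range(n_genomes)
            })
            otus = make_otu_table(rng.integers(0, 1000, (n_otus, n_samples)))
            hits = {}
            for otu in otus.feature_ids:
                if rng.random() < 0.8:  # some OTUs dropped
                    m = int(rng.integers(1, 4))
                    picked = rng.choice(sorted(db.genomes), size=min(m, n_genomes), replace=False)
                    hits[otu] = _hit(otu, *picked)
            fast = infer_ko_abundance(otus, hits, db, full_universe=True)
            slow = naive_ko_abundance(otus, hits, db, full_universe=True)
            assert list(fast.df.index) == list(slow.df.index)
            np.testing.assert_allclose(
                fast.matrix, slow.matrix, rtol=1e-9, atol=0
            )


class TestFloorCounts:
    def test_worked_values_and_dtype(self):
        table = KoAbundanceTable(pd.DataFrame(
            {"S1": [3.7, 5.0, 0.2]}, index=["K1", "K2", "K3"]
        ))
        floored = floor_counts(table)
        assert floored.df["S1"].tolist() == [3, 5, 0]
        assert floored.df["S1"].dtype == np.int64
        # the all-zero feature stays in the table
        assert "K3" in floored.df.index

    def test_never_increases_any_entry(self):
        rng = np.random.default_rng(77)
        values = rng.uniform(0, 50, size=(20, 4))
        table = KoAbundanceTable(pd.DataFrame(
            values, index=[f"K{i}" for i in range(20)], columns=list("ABCD")
        ))
        assert (floor_counts(table).matrix <= values).all()


class TestPassedFraction:
    def test_all_hit_is_one_none_is_zero(self):
        otus = make_otu_table([[10.0], [20.0]])
        both = {o: _hit(o, "g1") for o in otus.feature_ids}
        assert passed_fraction(otus, both).tolist() == [1.0]
        assert passed_fraction(otus, {}).tolist() == [0.0]

    def test_abundance_weighted(self):
        otus = make_otu_table([[90.0], [10.0]])
        frac = passed_fraction(otus, {"OTU1": _hit("OTU1", "g1")})
        assert frac["S1"] == 0.9

    def test_zero_total_sample_defined_as_zero(self):
        otus = make_otu_table([[0.0, 5.0]])
        frac = passed_fraction(otus, {"OTU1": _hit("OTU1", "g1")})
        assert frac["S1"] == 0.0 and frac["S2"] == 1.0
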