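"""Train/external splitting, directed oversampling and subset assembly."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scissile import (
    CleavageEvent,
    LabeledPattern,
    Peptide,
    SplitSpec,
    assemble_subsets,
    build_training_subsets,
    extract_patterns,
    oversampling_repeats,
    partition_negatives,
    split_train_external,
)

from conftest import random_events, random_peptides


def simple_corpus(n=10, events_per=1, seed=0):
    peptides = random_peptides(n, (12, 12), seed=seed)
    events = [CleavageEvent(p.id, 4 + i, "x")
              for p in peptides for i in range(events_per)]
    return peptides, events


class TestSplit:
    def test_uniform_events_split_8_2(self):
        peptides, events = simple_corpus(10)
        (trp, tre), (exp_, exe) = split_train_external(
            peptides, events, SplitSpec(0.8, seed=3))
        assert len(trp) == 8 and len(exp_) == 2
        assert len(tre) == 8 and len(exe) == 2

    def test_no_peptide_on_both_sides(self):
        peptides, events = simple_corpus(20, events_per=2)
        (trp, _), (exp_, _) = split_train_external(peptides, events,
                                                   SplitSpec(0.8, seed=1))
        assert not {p.id for p in trp} & {p.id for p in exp_}
        assert len(trp) + len(exp_) == 20

    def test_heterogeneous_counts_within_one_event(self):
        rng = np.random.default_rng(7)
        peptides = random_peptides(30, (15, 15), seed=2)
        events = []
        for p in peptides:
            for b in rng.choice(p.n_bonds, size=rng.integers(1, 6),
                                replace=False):
                events.append(CleavageEvent(p.id, int(b), "x"))
        (_, tre), (_, exe) = split_train_external(peptides, events,
                                                  SplitSpec(0.8, seed=11))
        target = 0.8 * len(events)
        assert abs(len(tre) - target) <= 1.0 + 1e-9

    def test_deterministic_given_seed(self):
        peptides, events = simple_corpus(12, events_per=3, seed=5)
        a = split_train_external(peptides, events, SplitSpec(0.8, seed=42))
        b = split_train_external(peptides, events, SplitSpec(0.8, seed=42))
        assert [p.id for p in a[0][0]] == [p.id for p in b[0][0]]
        assert [e.bond_index for e in a[1][1]] == [e.bond_index for e in b[1][1]]

    def test_too_few_substrates(self):
        peptides, events = simple_corpus(1)
        with pytest.raises(ValueError):
            split_train_external(peptides, events, SplitSpec(0.8, seed=0))

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            SplitSpec(fraction=1.0)


class TestOversampling:
    @pytest.mark.parametrize("M, expected", [
        (1, 1),      # 11/101 ~ 0.109, floored at one copy
        (10, 1),     # exactly 1.0
        (100, 6),    # exactly 5.5, rounds half up
        (340, 9),    # exactly 8.5
        (2100, 11),  # exactly 10.5
        (10**9, 11),
    ])
    def test_printed_formula(self, M, expected):
        assert oversampling_repeats(M) == expected

    def test_matches_fraction_oracle(self):
        for M in list(range(1, 2000)) + [10**4, 10**6]:
            x = Fraction(11 * M, 100 + M)
            expected = max(1, int(x + Fraction(1, 2)))  # round half up
            assert oversampling_repeats(M) == expected, M

    @settings(derandomize=True, max_examples=100)
    @given(M=st.integers(1, 10**7))
    def test_monotone_and_bounded(self, M):
        n = oversampling_repeats(M)
        assert 1 <= n <= 11
        assert n <= oversampling_repeats(M + 1)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            oversampling_repeats(0)


def negatives(n):
    """n distinct non-cleaved P1-P1' patterns over the natural amino acids."""
    from itertools import product

    aa = "ACDEGHILMNPQSTVWY"  # avoids K-F / R-F used as positives in tests
    pairs = [p for p in product(aa, repeat=2)][:n]
    assert len(pairs) == n
    return [LabeledPattern(pattern=p, cleaved=False, M=1) for p in pairs]


class TestPartitionNegatives:
    def test_95_by_30_gives_4_padded_partitions(self):
        parts = partition_negatives(negatives(95), 30, seed=1)
        assert len(parts) == 4
        assert all(len(p) == 30 for p in parts)
        # padding resamples, never duplicates within the padded partition
        assert len({p.pattern for p in parts[-1]}) == 30

    def test_exact_fit_no_padding(self):
        parts = partition_negatives(negatives(30), 30, seed=1)
        assert len(parts) == 1 and len(parts[0]) == 30

    def test_union_covers_all_negatives(self):
        negs = negatives(47)
        parts = partition_negatives(negs, 10, seed=3)
        seen = {p.pattern for part in parts for p in part}
        assert seen >= {n.pattern for n in negs}

    def test_fewer_negatives_than_positives_single_short_partition(self):
        parts = partition_negatives(negatives(4), 10, seed=0)
        assert len(parts) == 1 and len(parts[0]) == 4


class TestAssembleSubsets:
    def positives(self):
        return [LabeledPattern(tuple("KF"), True, M=3),
                LabeledPattern(tuple("RF"), True, M=10)]

    def test_one_subset_per_partition_same_positive_pool(self, table):
        parts = partition_negatives(negatives(6), 2, seed=0)
        subsets = assemble_subsets(self.positives(), parts, table)
        assert len(subsets) == len(parts) == 3
        pos_rows = [s.X[s.y == 1] for s in subsets]
        for rows in pos_rows[1:]:
            np.testing.assert_array_equal(rows, pos_rows[0])

    def test_oversampling_applied_within_subset(self, table):
        # M=10 -> 1 copy; M=150 -> round(11*150/250) = 7 copies
        pos = [LabeledPattern(tuple("KF"), True, M=10),
               LabeledPattern(tuple("RF"), True, M=150)]
        subsets = assemble_subsets(pos, [negatives(2)], table)
        s = subsets[0]
        assert s.patterns.count(("K", "F")) == 1
        assert s.patterns.count(("R", "F")) == 7

    def test_balanced_before_oversampling(self, table):
        # all M=1: no replication, so each subset is exactly balanced
        pos = [LabeledPattern((c, "A"), True, M=1) for c in "KRDE"]
        parts = partition_negatives(negatives(8), 4, seed=0)
        for s in assemble_subsets(pos, parts, table):
            assert s.n_pos == s.n_neg == 4

    def test_empty_positives_is_error(self, table):
        with pytest.raises(ValueError):
            assemble_subsets([], [negatives(3)], table)


class TestCsvExport:
    def test_pattern_frame_roundtrip(self, tmp_path, table):
        import pandas as pd

        from scissile.dataset import frame_to_patterns, patterns_to_frame

        peptides = random_peptides(10, (12, 20), seed=41)
        events = random_events(peptides, 0.1, seed=42, protease_id="x")
        pats = extract_patterns(peptides, events, k=1, protease_id="x")
        f = tmp_path / "dataset.csv"
        patterns_to_frame(pats, table).to_csv(f, index=False)
        back = frame_to_patterns(pd.read_csv(f))
        assert back == pats

    def test_feature_columns_match_table(self, table):
        from scissile.dataset import patterns_to_frame

        pats = [LabeledPattern(("K", "F"), True, M=2)]
        df = patterns_to_frame(pats, table)
        assert list(df.columns[:3]) == ["pattern", "label", "M"]
        assert df.shape[1] == 3 + 2 * table.d


class TestExtractPatterns:
    def test_labels_and_counts(self):
        p1 = Peptide(id="p1", blocks=tuple("AKFA"))
        p2 = Peptide(id="p2", blocks=tuple("GKFG"))
        ev = [CleavageEvent("p1", 1, "x")]
        pats = {lp.pattern: lp for lp in extract_patterns([p1, p2], ev, k=1)}
        assert pats[("K", "F")].cleaved and pats[("K", "F")].M == 2
        assert not pats[("A", "K")].cleaved

    def test_subset_count_matches_unique_pattern_ratio(self, table):
        peptides = random_peptides(60, (15, 30), seed=21)
        events = random_events(peptides, 0.06, seed=22, protease_id="x")
        pats = extract_patterns(peptides, events, k=4, protease_id="x")
        n_pos = sum(lp.cleaved for lp in pats)
        n_neg = len(pats) - n_pos
        subsets = build_training_subsets(peptides, events, table, k=4,
                                         protease_id="x", seed=1)
        assert len(subsets) == -(-n_neg // n_pos)  # ceil division

    def test_every_negative_reaches_some_subset(self, table):
        peptides = random_peptides(25, (12, 20), seed=31)
        events = random_events(peptides, 0.08, seed=32, protease_id="x")
        pats = extract_patterns(peptides, events, k=1, protease_id="x")
        neg_patterns = {lp.pattern for lp in pats if not lp.cleaved}
        subsets = build_training_subsets(peptides, events, table, k=1,
                                         protease_id="x", seed=2)
        seen = {pat for s in subsets for pat, lab in zip(s.patterns, s.y)
                if lab == 0}
        assert seen >= neg_patterns
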