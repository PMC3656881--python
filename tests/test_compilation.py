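"""Dataset compilation: labeling, conflicts, dedup, domain filtering."""

import itertools

import numpy as np
import pytest

from sh2pep.compilation import (
    DomainDataset,
    InteractionRecord,
    assign_labels,
    compile_datasets,
    deduplicate_positives,
    filter_domains,
    group_by_domain,
    label_from_kd,
    resolve_conflicts,
)
from sh2pep.peptides import AMINO_ACIDS, Peptide


def _windows(n, start=0):
    """Deterministic distinct 7-mer windows."""
    out = []
    for combo in itertools.islice(itertools.product(AMINO_ACIDS, repeat=3), start, start + n):
        out.append(Peptide("".join(combo[:2]) + "Y" + combo[2] + "AAA"))
    return out


def _rec(domain, pep, kd=None, label=None, source="src"):
    return InteractionRecord(domain, pep, kd, label, source)


class TestLabelFromKd:
    @pytest.mark.parametrize(
        "kd, expected",
        [(160.0, 1), (1999.9, 1), (2000.0, -1), (3500.0, -1)],
    )
    def test_threshold_is_strict_at_2000(self, kd, expected):
        assert label_from_kd(kd) == expected

    @pytest.mark.parametrize("kd", [0.0, -5.0, None])
    def test_invalid_kd_rejected(self, kd):
        with pytest.raises(ValueError):
            label_from_kd(kd)

    def test_explicit_label_wins_over_kd_with_warning(self):
        rec = _rec("D", _windows(1)[0], kd=100.0, label=-1)
        with pytest.warns(UserWarning, match="overrides"):
            out = assign_labels([rec])
        assert out[0].label == -1


class TestResolveConflicts:
    def test_conflicting_pair_removed_from_both_sides(self):
        p = _windows(1)[0]
        recs = [_rec("D", p, label=1, source="a"), _rec("D", p, label=-1, source="b")]
        kept, n_conflicts, n_dup = resolve_conflicts(recs)
        assert kept == [] and n_conflicts == 1 and n_dup == 0

    def test_agreeing_duplicates_collapse(self):
        p = _windows(1)[0]
        recs = [_rec("D", p, label=1, source="a"), _rec("D", p, label=1, source="b")]
        kept, n_conflicts, n_dup = resolve_conflicts(recs)
        assert len(kept) == 1 and n_conflicts == 0 and n_dup == 1

    def test_toy_table_with_two_conflicts(self):
        """10 records, 2 conflicting pairs -> 6 retained (exhaustive toy)."""
        w = _windows(8)
        recs = [_rec("D", p, label=1) for p in w[:6]]
        recs += [_rec("D", w[6], label=1), _rec("D", w[6], label=-1, source="b")]
        recs += [_rec("D", w[7], label=1), _rec("D", w[7], label=-1, source="b")]
        kept, n_conflicts, n_dup = resolve_conflicts(recs)
        assert len(kept) == 6 and n_conflicts == 2

    def test_idempotent(self):
        w = _windows(6)
        recs = [_rec("D", p, label=(1 if i % 2 else -1)) for i, p in enumerate(w)]
        recs.append(_rec("D", w[0], label=1))  # conflict with the -1 at w[0]
        once, n1, d1 = resolve_conflicts(recs)
        twice, n2, d2 = resolve_conflicts(once)
        assert twice == once and n2 == 0 and d2 == 0

    def test_conservation_partition(self, rng):
        """input = retained + conflict rows + duplicates, for random tables."""
        w = _windows(12)
        recs = []
        for _ in range(60):
            recs.append(
                _rec("D", w[rng.integers(12)], label=int(rng.choice([1, -1])))
            )
        kept, n_conflicts, n_dup = resolve_conflicts(recs)
        conflict_keys = set()
        by_key = {}
        for r in recs:
            by_key.setdefault(r.key, set()).add(r.label)
        n_conflict_rows = sum(
            1 for r in recs if len(by_key[r.key]) == 2
        )
        assert len(kept) + n_conflict_rows + n_dup == len(recs)

    def test_unlabeled_records_rejected(self):
        rec = _rec("D", _windows(1)[0], kd=100.0)
        with pytest.raises(ValueError, match="labeled"):
            resolve_conflicts([rec])


class TestDeduplicatePositives:
    def test_simple_overlap(self):
        a, b, c = _windows(3)
        primary = {("D", a.residues), ("D", b.residues)}
        others = {"x": [_rec("D", b, label=1, source="x"), _rec("D", c, label=1, source="x")]}
        unique, n_unique, n_shared = deduplicate_positives(primary, others)
        assert [r.peptide for r in unique["x"]] == [c]
        assert n_unique == {"x": 1} and n_shared == {"x": 1}

    def test_replays_published_microarray_arithmetic(self):
        """160 and 314 positives with 112 and 135 shared -> 48 + 179 = 227 unique."""
        w = _windows(700)
        primary_peps = w[:400]
        primary = {("D", p.residues) for p in primary_peps}
        ds2 = [_rec("D", p, label=1, source="II") for p in primary_peps[:112] + w[400:448]]
        ds3 = [_rec("D", p, label=1, source="III") for p in primary_peps[100:235] + w[448:627]]
        assert len(ds2) == 160 and len(ds3) == 314
        assert len(ds2) + len(ds3) == 474  # total microarray positives
        unique, n_unique, n_shared = deduplicate_positives(primary, {"II": ds2, "III": ds3})
        assert n_unique == {"II": 48, "III": 179}
        assert n_shared == {"II": 112, "III": 135}
        assert sum(n_unique.values()) == 227


class TestFilterDomains:
    def _dataset(self, domain, n_pos):
        return DomainDataset(domain, positives=_windows(n_pos), negatives=[])

    def test_boundary_below_40_dropped(self):
        kept, dropped = filter_domains({"A": self._dataset("A", 39)})
        assert kept == {} and dropped == {"A": 39}

    def test_boundary_at_40_retained(self):
        kept, dropped = filter_domains({"A": self._dataset("A", 40)})
        assert "A" in kept and dropped == {}

    def test_61_domains_10_below_threshold_leaves_51(self):
        datasets = {}
        for i in range(61):
            n = 39 if i < 10 else 40
            datasets[f"D{i:02d}"] = self._dataset(f"D{i:02d}", n)
        kept, dropped = filter_domains(datasets)
        assert len(kept) == 51 and len(dropped) == 10


class TestDomainDataset:
    def test_rejects_peptide_with_both_labels(self):
        p = _windows(1)[0]
        with pytest.raises(ValueError, match="both labels"):
            DomainDataset("D", positives=[p], negatives=[p])

    def test_rejects_duplicate_instances(self):
        p = _windows(1)[0]
        with pytest.raises(ValueError, match="duplicate"):
            DomainDataset("D", positives=[p, p], negatives=[])

    def test_encoded_shapes_and_labels(self):
        w = _windows(5)
        ds = DomainDataset("D", positives=w[:2], negatives=w[2:4], unlabeled=w[4:])
        X, y, pool = ds.encoded("full20")
        assert X.shape == (4, 120) and pool.shape == (1, 120)
        assert list(y) == [1, 1, -1, -1]


class TestCompilePipeline:
    def test_end_to_end_counts(self):
        w = _windows(120)
        recs = []
        # primary source: 50 positives for D1, 30 for D2
        for p in w[:50]:
            recs.append(_rec("D1", p, label=1, source="arrays"))
        for p in w[50:80]:
            recs.append(_rec("D2", p, label=1, source="arrays"))
        # microarray: negatives for D1, incl. 5 conflicting with primary positives
        for p in w[80:110]:
            recs.append(_rec("D1", p, kd=3000.0, source="chip"))
        for p in w[:5]:
            recs.append(_rec("D1", p, kd=3000.0, source="chip"))
        # microarray positives duplicating primary (should be deduped, not conflict)
        for p in w[5:15]:
            recs.append(_rec("D1", p, kd=100.0, source="chip"))
        datasets, report = compile_datasets(recs, primary_source="arrays", min_positives=40)
        assert report.n_conflict_pairs == 5
        assert report.n_shared_positives == {"chip": 10}
        assert report.n_unique_positives == {"chip": 0}
        # D2 has 30 < 40 positives -> dropped; D1 keeps 45 positives, 30 negatives
        assert list(datasets) == ["D1"]
        assert datasets["D1"].n_pos == 45 and datasets["D1"].n_neg == 30
        assert report.dropped_domains == {"D2": 30}
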