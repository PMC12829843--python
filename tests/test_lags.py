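import datetime as dt
import itertools

import numpy as np
import pytest

from taxalag import (compute_lags, cumulative_within, is_evenly_distributed,
                     seasonality_matrix, segment_trips, unique_sorted_dates)
from taxalag.dates import CollectionDate, DatePrecision
from taxalag.records import TypeSeriesRecord

from _oracles import trips_by_components


def _event(date):
    return CollectionDate(date.isoformat(), date, DatePrecision.DAY, 0)


def _record(dates, pub, species="sp1", region="Ecuador", genus="G"):
    return TypeSeriesRecord(
        species=species, genus=genus, region=region,
        publication_date=pub, publication_id="p1",
        collection_events=tuple(_event(d) for d in dates),
        n_authors=1, n_types=1, n_species_in_paper=1, genetics=False,
        genus_richness=1)


def test_unique_sorted_dates_dedupes_and_sorts():
    d = [dt.date(2007, 6, 10), dt.date(2005, 1, 1), dt.date(2005, 1, 1)]
    rec = _record(d, dt.date(2010, 1, 1))
    assert unique_sorted_dates(rec) == [dt.date(2005, 1, 1),
                                        dt.date(2007, 6, 10)]


def test_lag_decomposition_example_and_additivity():
    rec = _record([dt.date(2000, 1, 1), dt.date(2005, 1, 1)],
                  dt.date(2010, 1, 1))
    lags = compute_lags(rec)
    assert lags.collection_y == pytest.approx(1827 / 365.25)
    assert lags.description_y == pytest.approx(1826 / 365.25)
    assert lags.overall_y == pytest.approx(3653 / 365.25)
    assert abs(lags.overall_y -
               (lags.collection_y + lags.description_y)) < 1e-9


def test_single_date_gives_zero_collection():
    rec = _record([dt.date(2009, 6, 1)], dt.date(2010, 6, 1))
    lags = compute_lags(rec)
    assert lags.collection_y == 0.0
    assert lags.n_unique_dates == 1 and lags.n_trips == 1


def test_additivity_on_random_records():
    """overall = collection + description to 1e-9 years, 10^4 draws."""
    rng = np.random.default_rng(42)
    base = dt.date(1950, 1, 1)
    worst = 0.0
    for _ in range(10_000):
        a = int(rng.integers(0, 20_000))
        b = a + int(rng.integers(0, 20_000))
        p = b + 1 + int(rng.integers(0, 10_000))
        rec = _record([base + dt.timedelta(days=a),
                       base + dt.timedelta(days=b)],
                      base + dt.timedelta(days=p))
        lags = compute_lags(rec)
        worst = max(worst, abs(
            lags.overall_y - (lags.collection_y + lags.description_y)))
    assert worst < 1e-9


def test_event_order_does_not_matter():
    dates = [dt.date(2003, 5, 1), dt.date(2001, 2, 3), dt.date(2002, 7, 9)]
    pub = dt.date(2010, 1, 1)
    a = compute_lags(_record(dates, pub))
    b = compute_lags(_record(dates[::-1], pub))
    assert a == b


class TestSegmentTrips:
    def test_boundary_gap_of_exactly_30_days_joins(self):
        d = [dt.date(2010, 1, 1), dt.date(2010, 1, 31)]
        assert len(segment_trips(d, 30)) == 1

    def test_gap_of_31_days_splits(self):
        d = [dt.date(2010, 1, 1), dt.date(2010, 2, 1)]
        assert len(segment_trips(d, 30)) == 2

    def test_mixed_gaps(self):
        d = [dt.date(2010, 1, 1), dt.date(2010, 1, 20),
             dt.date(2010, 3, 15)]
        trips = segment_trips(d, 30)
        assert [len(t) for t in trips] == [2, 1]

    def test_requires_strictly_increasing_dates(self):
        d = [dt.date(2010, 1, 1), dt.date(2010, 1, 1)]
        with pytest.raises(ValueError):
            segment_trips(d)

    def test_exhaustive_triples_match_component_oracle(self):
        """All date triples within a 120-day window group exactly as the
        brute-force connected-components oracle says."""
        base = dt.date(2015, 3, 1)
        for offs in itertools.combinations(range(0, 121), 3):
            dates = [base + dt.timedelta(days=o) for o in offs]
            assert segment_trips(dates, 30) == \
                trips_by_components(dates, 30)

    def test_increasing_gap_threshold_never_adds_trips(self):
        rng = np.random.default_rng(7)
        base = dt.date(2000, 1, 1)
        for _ in range(200):
            offs = np.unique(rng.integers(0, 2000, size=8))
            dates = [base + dt.timedelta(days=int(o)) for o in offs]
            n_prev = None
            for gap in (10, 30, 60, 120, 365):
                n = len(segment_trips(dates, gap))
                assert n_prev is None or n <= n_prev
                n_prev = n


def test_cumulative_within_fractions():
    assert cumulative_within([1, 6, 20], [5, 10]) == \
        pytest.approx([1 / 3, 2 / 3])
    assert cumulative_within([1, 6, 20], [25])[0] == 1.0
    out = cumulative_within([1, 6, 20], [2, 5, 10, 30])
    assert all(a <= b for a, b in zip(out, out[1:]))
    with pytest.raises(ValueError):
        cumulative_within([], [5])


def test_seasonality_counts_unique_dates_per_cell():
    recs = [
        _record([dt.date(2007, 2, 14), dt.date(2007, 2, 14),
                 dt.date(2008, 12, 6)], dt.date(2010, 1, 1), species="a"),
        # a second species on the same calendar day counts again
        _record([dt.date(2007, 2, 14)], dt.date(2011, 1, 1), species="b"),
    ]
    m = seasonality_matrix(recs)
    assert m.counts.loc[2, 2007] == 2
    assert m.counts.loc[12, 2008] == 1
    assert m.total() == 3


def test_evenness_criterion_boundary():
    recs = [_record([dt.date(2000 + i % 3, m, 1)
                     for m in range(1, 13) for i in [0]],
                    dt.date(2005, 1, 1))]
    m = seasonality_matrix(recs)
    even, ratios = is_evenly_distributed(m)
    assert even and ratios.min() == 1.0

    counts = m.counts.copy()
    counts.loc[:, :] = 0
    counts.loc[1, 2000] = 100
    counts.loc[2, 2000] = 39
    for mo in range(3, 13):
        counts.loc[mo, 2000] = 60
    m.counts = counts
    even, ratios = is_evenly_distributed(m)
    assert not even  # 39 < 40% of the 100-specimen peak

    counts.loc[2, 2000] = 40
    even, _ = is_evenly_distributed(m)
    assert even  # "at least 40%" is inclusive


def test_pooling_regions_equals_global(small_records, small_lags):
    per_region = []
    for region in sorted({r.region for r in small_records}):
        per_region.extend(
            small_lags[small_lags.region == region]["overall_y"].tolist())
    assert sorted(per_region) == sorted(small_lags["overall_y"].tolist())
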