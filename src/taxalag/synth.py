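"""Synthetic type-series datasets with known ground truth.

The generator emulates the statistical structure the analysis assumes, so
every pipeline stage can be exercised without any external data:

* four regions with realistic regional sample sizes and genus pools;
* multi-trip collection histories whose inter-trip gaps stay strictly
  above the 30-day segmentation threshold (plus a buffer, default 3 days)
  and whose within-trip gaps stay strictly below it, so the true trip
  count is unambiguous;
* a log-scale linear model for the description lag,
  log(description_y) = beta0 + X beta + u_genus + v_region + eps,
  which is exactly the mixed model the inference module fits;
* right-skewed collection lags (point mass near zero for single-trip
  species plus a heavy lognormal tail), seasonal collection months, and
  optional imprecise-date masking of the emitted date strings.

Seeds are split hierarchically (one stream per species) so enlarging the
dataset leaves earlier species' draws unchanged.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dates import days_in_month, parse_date_text
from .records import TypeSeriesRecord

# stream tags for hierarchical seeding
_TAG_REGION_EFF, _TAG_GENUS, _TAG_SPECIES, _TAG_PAPERS, _TAG_MASK = 1, 2, 3, 4, 5

DEFAULT_REGION_SIZES = {
    "Ecuador": 208, "India": 204, "Madagascar": 215, "Melanesia": 269,
}

# peaked wet-season collecting for Madagascar (austral summer) and India
# (monsoon); near-even collecting for Ecuador and Melanesia
_EVEN = [1.0] * 12
DEFAULT_MONTH_WEIGHTS = {
    "Ecuador": _EVEN,
    "Melanesia": _EVEN,
    "Madagascar": [5, 5, 4, 2, 1, 0.5, 0.5, 0.5, 1, 1.5, 2.5, 4],
    "India": [0.5, 0.5, 1, 1.5, 2, 5, 6, 5, 4, 2, 1, 0.5],
}

DEFAULT_BETA = {
    "genetics": 0.15,
    "n_authors": -0.05,
    "n_types": 0.0,
    "n_species_in_paper": 0.04,
    "n_trips": -0.08,
    "genus_richness": -0.001,
}


@dataclass(frozen=True)
class GeneratorConfig:
    region_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_REGION_SIZES))
    n_genera_per_region: int = 15
    beta0: float = 1.7
    beta: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BETA))
    sigma2_genus: float = 0.20
    sigma2_region: float = 0.05
    sigma2_resid: float = 0.50
    # collection-history law
    p_single_trip: float = 0.531
    gap_log_mean: float = math.log(500.0)
    gap_log_sd: float = 1.1
    gap_days: int = 30
    buffer_days: int = 3
    within_extra_dates_lambda: float = 1.5
    # covariate laws
    authors_base_lambda: float = 1.5
    authors_year_slope: float = 0.12
    types_lambda: float = 7.0
    paper_extra_lambda: float = 0.7
    genetics_min: float = 0.15
    genetics_max: float = 0.95
    genetics_midyear: float = 2010.0
    genetics_rate: float = 1 / 3
    # imprecise-date masking probabilities; the default masks only to the
    # symmetric day-range dialect, which preserves midpoints exactly and so
    # keeps true trip counts identifiable (month/year masking shifts
    # midpoints by up to 15/183 days and is opt-in for sensitivity runs)
    mask_p_day_range: float = 0.08
    mask_p_month: float = 0.0
    mask_p_year: float = 0.0
    # description window
    first_year: int = 2000
    last_year: int = 2023
    seed: int = 0

    def validate(self) -> None:
        probs = [self.p_single_trip, self.genetics_min, self.genetics_max,
                 self.mask_p_day_range, self.mask_p_month, self.mask_p_year]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.mask_p_day_range + self.mask_p_month + self.mask_p_year > 1:
            raise ValueError("masking probabilities sum above 1")
        if min(self.sigma2_genus, self.sigma2_region, self.sigma2_resid) < 0:
            raise ValueError("variance components must be >= 0")
        if self.buffer_days < 1 or self.buffer_days >= self.gap_days:
            raise ValueError("buffer_days must be in [1, gap_days)")
        if self.first_year > self.last_year:
            raise ValueError("first_year must be <= last_year")
        if any(n < 1 for n in self.region_sizes.values()):
            raise ValueError("region sizes must be >= 1")

    def with_masking(self, p_day_range: float, p_month: float,
                     p_year: float) -> "GeneratorConfig":
        return replace(self, mask_p_day_range=p_day_range,
                       mask_p_month=p_month, mask_p_year=p_year)


def _rng(seed: int, *keys: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *keys]))


def _seasonal_month(rng: np.random.Generator, weights) -> int:
    w = np.asarray(weights, dtype=float)
    return int(rng.choice(12, p=w / w.sum())) + 1


@dataclass
class _SpeciesDraw:
    region: str
    index: int
    genus: str
    genus_richness: int
    u_genus: float
    v_region: float
    eps: float
    target_year: int
    n_trips: int
    offsets: list[int]  # day offsets of all distinct dates from the first
    month: int
    day: int
    n_authors: int
    n_types: int
    genetics: bool


def _collection_offsets(rng: np.random.Generator,
                        cfg: GeneratorConfig) -> tuple[int, list[int]]:
    """True trip count and day offsets of all collection dates from the
    first.  Inter-trip gaps are > gap_days + buffer; within-trip
    consecutive gaps are <= gap_days - buffer, so segmentation at the
    threshold recovers the trips exactly."""
    n_trips = int(rng.geometric(cfg.p_single_trip))
    within_max = cfg.gap_days - cfg.buffer_days
    offsets = [0]
    for trip in range(n_trips):
        if trip > 0:
            gap = cfg.gap_days + cfg.buffer_days + 1 + int(
                rng.lognormal(cfg.gap_log_mean, cfg.gap_log_sd))
            offsets.append(offsets[-1] + gap)
        extra = int(rng.poisson(cfg.within_extra_dates_lambda))
        for _ in range(extra):
            offsets.append(offsets[-1] + int(rng.integers(1, within_max + 1)))
    return n_trips, offsets


def generate(config: GeneratorConfig | None = None
             ) -> tuple[list[TypeSeriesRecord], pd.DataFrame]:
    """Generate records plus a per-species truth table.

    Returns ``(records, truth)`` where ``truth`` holds the true trip
    counts, lag periods, random-effect draws and the parameters used.
    Fully reproducible from ``config.seed``.
    """
    cfg = config or GeneratorConfig()
    cfg.validate()
    seed = cfg.seed
    regions = sorted(cfg.region_sizes)

    draws: dict[str, list[_SpeciesDraw]] = {}
    for r_idx, region in enumerate(regions):
        v_region = float(_rng(seed, _TAG_REGION_EFF, r_idx).normal(
            0.0, math.sqrt(cfg.sigma2_region)))
        grng = _rng(seed, _TAG_GENUS, r_idx)
        n_gen = cfg.n_genera_per_region
        richness = np.clip(
            np.round(grng.lognormal(3.0, 1.0, size=n_gen)), 1, 400
        ).astype(int)
        u_genus = grng.normal(0.0, math.sqrt(cfg.sigma2_genus), size=n_gen)
        genus_weights = richness / richness.sum()
        month_w = DEFAULT_MONTH_WEIGHTS.get(region, _EVEN)

        out = []
        for i in range(cfg.region_sizes[region]):
            rng = _rng(seed, _TAG_SPECIES, r_idx, i)
            g = int(rng.choice(n_gen, p=genus_weights))
            year = int(rng.integers(cfg.first_year, cfg.last_year + 1))
            n_trips, offsets = _collection_offsets(rng, cfg)
            lam_authors = (cfg.authors_base_lambda
                           + cfg.authors_year_slope * (year - cfg.first_year))
            p_gen = cfg.genetics_min + (
                cfg.genetics_max - cfg.genetics_min) / (
                1.0 + math.exp(-(year - cfg.genetics_midyear)
                               * cfg.genetics_rate))
            out.append(_SpeciesDraw(
                region=region, index=i,
                genus=f"{region[:3]}_genus{g:02d}",
                genus_richness=int(richness[g]),
                u_genus=float(u_genus[g]), v_region=v_region,
                eps=float(rng.normal(0.0, math.sqrt(cfg.sigma2_resid))),
                target_year=year, n_trips=n_trips, offsets=offsets,
                month=_seasonal_month(rng, month_w),
                day=int(rng.integers(1, 29)),
                n_authors=1 + int(rng.poisson(lam_authors)),
                n_types=1 + int(rng.poisson(cfg.types_lambda)),
                genetics=bool(rng.random() < p_gen),
            ))
        draws[region] = out

    # paper grouping: species of a region sharing a target year are
    # partitioned into papers; paper size becomes the per-species covariate
    paper_of: dict[tuple[str, int], tuple[str, int]] = {}
    for r_idx, region in enumerate(regions):
        prng = _rng(seed, _TAG_PAPERS, r_idx)
        by_year: dict[int, list[int]] = {}
        for d in draws[region]:
            by_year.setdefault(d.target_year, []).append(d.index)
        for year in sorted(by_year):
            idxs = list(by_year[year])
            prng.shuffle(idxs)
            k = 0
            while idxs:
                size = 1 + int(prng.poisson(cfg.paper_extra_lambda))
                chunk, idxs = idxs[:size], idxs[size:]
                pid = f"{region}-{year}-p{k:03d}"
                for i in chunk:
                    paper_of[(region, i)] = (pid, len(chunk))
                k += 1

    records: list[TypeSeriesRecord] = []
    truth_rows = []
    for region in regions:
        for d in draws[region]:
            pid, paper_size = paper_of[(region, d.index)]
            x = {
                "genetics": float(d.genetics),
                "n_authors": float(d.n_authors),
                "n_types": float(d.n_types),
                "n_species_in_paper": float(paper_size),
                "n_trips": float(d.n_trips),
                "genus_richness": float(d.genus_richness),
            }
            eta = (cfg.beta0
                   + sum(cfg.beta.get(c, 0.0) * v for c, v in x.items())
                   + d.u_genus + d.v_region + d.eps)
            desc_days = max(1, int(round(math.exp(eta) * 365.25)))
            span_days = d.offsets[-1]

            first = _anchor_first_date(d, span_days + desc_days,
                                       cfg.first_year, cfg.last_year)
            dates = [first + dt.timedelta(days=o) for o in d.offsets]
            pub = dates[-1] + dt.timedelta(days=desc_days)
            events = tuple(parse_date_text(day.isoformat())
                           for day in dates)
            species = f"{region[:3]}_sp{d.index:04d}"
            records.append(TypeSeriesRecord(
                species=species, genus=d.genus, region=region,
                publication_date=pub, publication_id=pid,
                collection_events=events,
                n_authors=d.n_authors, n_types=d.n_types,
                n_species_in_paper=paper_size, genetics=d.genetics,
                genus_richness=d.genus_richness,
            ))
            truth_rows.append({
                "species": species, "region": region, "genus": d.genus,
                "n_trips": d.n_trips, "n_unique_dates": len(dates),
                "collection_y": span_days / 365.25,
                "description_y": desc_days / 365.25,
                "overall_y": (span_days + desc_days) / 365.25,
                "u_genus": d.u_genus, "v_region": d.v_region,
                "eps": d.eps, "eta": eta,
                "publication_year": pub.year,
            })
    truth = pd.DataFrame(truth_rows)
    if cfg.mask_p_day_range + cfg.mask_p_month + cfg.mask_p_year > 0:
        records, _ = mask_imprecision(records, cfg, seed)
    return records, truth


def _anchor_first_date(d: _SpeciesDraw, total_days: int,
                       first_year: int, last_year: int) -> dt.date:
    """First collection date with the drawn seasonal month/day, anchored
    so the publication year equals the drawn target year (or the nearest
    achievable year inside the window)."""
    y1 = d.target_year - int(round(total_days / 365.2425))
    best = None
    for dy in (0, -1, 1, -2, 2):
        first = dt.date(y1 + dy, d.month, d.day)
        pub_year = (first + dt.timedelta(days=total_days)).year
        miss = abs(pub_year - d.target_year)
        if best is None or miss < best[0]:
            best = (miss, first)
        if miss == 0:
            break
    return best[1]


def mask_imprecision(records: list[TypeSeriesRecord],
                     config: GeneratorConfig, seed: int | None = None
                     ) -> tuple[list[TypeSeriesRecord], pd.DataFrame]:
    """Degrade day-precision raw date strings to range/month/year dialects.

    Returns the masked records plus a log with the worst-case midpoint
    shift per masked event (0 days for a symmetric day range, <= 15 for
    month precision, <= 183 for year precision), so downstream tests can
    bound the induced lag error.
    """
    cfg = config
    seed = cfg.seed if seed is None else seed
    rng = _rng(seed, _TAG_MASK)
    out: list[TypeSeriesRecord] = []
    log_rows = []
    for rec in records:
        new_events = []
        for j, ev in enumerate(rec.collection_events):
            raw = ev.raw_text
            new_raw = None
            bound = 0
            if ev.precision.value == "day":
                u = rng.random()
                date = ev.resolved
                if u < cfg.mask_p_day_range:
                    lo, hi = date.day - 1, date.day + 1
                    if lo >= 1 and hi <= days_in_month(date.year, date.month):
                        new_raw = (f"{lo}–{hi} "
                                   f"{date.strftime('%B')} {date.year}")
                        bound = 0  # symmetric range keeps the midpoint
                elif u < cfg.mask_p_day_range + cfg.mask_p_month:
                    new_raw = f"{date.strftime('%B')} {date.year}"
                    bound = 15
                elif (u < cfg.mask_p_day_range + cfg.mask_p_month
                        + cfg.mask_p_year):
                    new_raw = str(date.year)
                    bound = 183
            if new_raw is not None:
                new_ev = parse_date_text(new_raw)
                log_rows.append({
                    "species": rec.species, "event": j,
                    "precision": new_ev.precision.value,
                    "max_shift_days": bound,
                    "actual_shift_days":
                        abs((new_ev.resolved - ev.resolved).days),
                })
                new_events.append(new_ev)
            else:
                new_events.append(ev)
        out.append(TypeSeriesRecord(
            species=rec.species, genus=rec.genus, region=rec.region,
            publication_date=rec.publication_date,
            publication_id=rec.publication_id,
            collection_events=tuple(new_events),
            n_authors=rec.n_authors, n_types=rec.n_types,
            n_species_in_paper=rec.n_species_in_paper,
            genetics=rec.genetics, genus_richness=rec.genus_richness,
        ))
    cols = ["species", "event", "precision", "max_shift_days",
            "actual_shift_days"]
    return out, pd.DataFrame(log_rows, columns=cols)
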