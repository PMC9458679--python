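"""Synthetic ascertained referral cohorts with known ground truth.

The generator emulates the data-generating structure of a mixed-ancestry
FMF referral cohort:

1. **Pedigree** — each subject's four grandparent origins are drawn from a
   weighted set of countries.  With probability ``endogamy`` all four share
   one country; otherwise each parental side independently shares a country
   with probability ``side_coherence``, else its two slots are independent
   draws.
2. **Genotype** — each parental allele is drawn from the equal mixture of
   that side's two grandparent populations, using per-country allele
   frequency vectors over the five founder variants (the remainder is wild
   type).  This samples grandparent-origin-conditional allele frequencies
   directly rather than simulating parental genotypes; the two are
   equivalent in expectation, which is what the downstream inference sees.
3. **Ascertainment** — referral cohorts contain only genotype-positive
   subjects; with ``ascertain=True`` subjects with two wild-type alleles
   are discarded (a random retained count; :func:`simulate_retained`
   resamples until a requested count is reached).
4. **Missingness** — after ascertainment each grandparent slot is blanked
   independently with probability ``missingness``.  Subjects who thereby
   lose a whole parental side stay in the cohort; the origin-score encoder
   excludes them, as in the real pipeline.

Every run is reproducible from the config seed.  Two presets are provided:
``null_config`` (identical frequencies in all 26 countries — no
origin-variant association) and ``paper_like_config`` (three planted
geographic clusters, one per common variant).  Preset frequencies are
invented qualitative stand-ins, not estimates from any real cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import yaml

from .cohort_io import WT, VARIANTS, Cohort, ReferralRecord

__all__ = [
    "PopulationSpec",
    "SimulationConfig",
    "sample_origins",
    "sample_genotype",
    "simulate_cohort",
    "simulate_retained",
    "null_config",
    "paper_like_config",
    "planted_countries",
]


@dataclass(frozen=True)
class PopulationSpec:
    """One source country: sampling weight and founder-variant allele
    frequencies (summing to at most 1; the remainder is WT)."""

    country: str
    weight: float = 1.0
    frequencies: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError(f"{self.country}: weight must be >= 0")
        freqs = dict(self.frequencies)
        for v, q in freqs.items():
            if v not in VARIANTS:
                raise ValueError(f"{self.country}: unknown variant {v!r}")
            if not 0.0 <= q <= 1.0:
                raise ValueError(f"{self.country}: frequency of {v} out of [0,1]")
        if sum(freqs.values()) > 1.0 + 1e-12:
            raise ValueError(f"{self.country}: variant frequencies sum to more than 1")
        object.__setattr__(self, "frequencies", freqs)

    def allele_probs(self) -> np.ndarray:
        """Probabilities over (WT, *VARIANTS)."""
        qs = np.array([self.frequencies.get(v, 0.0) for v in VARIANTS])
        return np.r_[1.0 - qs.sum(), qs]


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-generation parameters; doubles as the ground-truth record."""

    populations: tuple[PopulationSpec, ...]
    n_subjects: int
    endogamy: float = 0.5
    side_coherence: float = 0.8
    missingness: float = 0.1
    female_fraction: float = 0.52
    ascertain: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "populations", tuple(self.populations))
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name in ("endogamy", "side_coherence", "missingness", "female_fraction"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")
        if not self.populations:
            raise ValueError("at least one population is required")
        if sum(p.weight for p in self.populations) <= 0:
            raise ValueError("total population weight must be positive")

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["populations"] = [asdict(p) for p in self.populations]
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        pops = tuple(PopulationSpec(**p) for p in data.pop("populations"))
        return cls(populations=pops, **data)


def _country_sampler(config: SimulationConfig):
    countries = [p.country for p in config.populations]
    w = np.array([p.weight for p in config.populations], dtype=float)
    probs = w / w.sum()
    return countries, probs


def sample_origins(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[str, str, str, str]:
    """Draw the four grandparent countries for one subject."""
    countries, probs = _country_sampler(config)

    def draw() -> str:
        return countries[rng.choice(len(countries), p=probs)]

    if rng.random() < config.endogamy:
        c = draw()
        return (c, c, c, c)
    slots = []
    for _side in range(2):
        if rng.random() < config.side_coherence:
            c = draw()
            slots += [c, c]
        else:
            slots += [draw(), draw()]
    return tuple(slots)  # type: ignore[return-value]


def sample_genotype(
    slots: Sequence[str],
    populations: Mapping[str, PopulationSpec],
    rng: np.random.Generator,
) -> tuple[str, str]:
    """Draw the two allele calls given grandparent origins.

    The paternal allele comes from the equal mixture of the two paternal
    grandparents' frequency vectors (pick a grandparent uniformly, then an
    allele by that country's frequencies); likewise maternally.  The two
    alleles are independent.
    """
    alleles = []
    for side in (slots[:2], slots[2:]):
        country = side[int(rng.random() < 0.5)]
        if country not in populations:
            raise KeyError(f"country {country!r} has no population spec")
        probs = populations[country].allele_probs()
        alleles.append(((WT,) + VARIANTS)[rng.choice(len(probs), p=probs)])
    return alleles[0], alleles[1]


def _draw_subject(
    i: int,
    config: SimulationConfig,
    populations: Mapping[str, PopulationSpec],
    rng: np.random.Generator,
) -> ReferralRecord:
    slots = sample_origins(config, rng)
    a1, a2 = sample_genotype(slots, populations, rng)
    sex = "female" if rng.random() < config.female_fraction else "male"
    return ReferralRecord(
        subject_id=f"S{i:05d}",
        sex=sex,
        gp_paternal_1=slots[0],
        gp_paternal_2=slots[1],
        gp_maternal_1=slots[2],
        gp_maternal_2=slots[3],
        allele_1=a1,
        allele_2=a2,
    )


def _apply_missingness(
    records: list[ReferralRecord], missingness: float, rng: np.random.Generator
) -> list[ReferralRecord]:
    if missingness == 0.0:
        return records
    out = []
    for rec in records:
        keep = rng.random(4) >= missingness
        slots = tuple(c if k else "" for c, k in zip(rec.grandparents, keep))
        out.append(rec.with_slots(slots[:2], slots[2:]))
    return out


def simulate_cohort(config: SimulationConfig) -> tuple[Cohort, SimulationConfig]:
    """Generate a cohort of ``n_subjects`` pedigrees and genotypes.

    With ``ascertain=True`` only genotype-positive subjects are retained
    (the retained count is random).  Missingness is applied after
    ascertainment.  Returns the cohort and the config as the ground-truth
    record; identical configs give byte-identical cohorts.
    """
    rng = np.random.default_rng(config.seed)
    populations = {p.country: p for p in config.populations}
    records = [
        _draw_subject(i + 1, config, populations, rng)
        for i in range(config.n_subjects)
    ]
    if config.ascertain:
        records = [r for r in records if r.alleles != (WT, WT)]
        if not records:
            raise RuntimeError(
                "ascertainment removed every subject; variant frequencies are "
                f"too low for n_subjects={config.n_subjects}"
            )
    records = _apply_missingness(records, config.missingness, rng)
    registry = [p.country for p in config.populations]
    return Cohort.from_records(records, extra_countries=registry), config


def simulate_retained(
    config: SimulationConfig, n_retained: int
) -> tuple[Cohort, SimulationConfig]:
    """Like :func:`simulate_cohort` but resamples subjects until exactly
    ``n_retained`` pass ascertainment (convenience for fixed-size studies)."""
    rng = np.random.default_rng(config.seed)
    populations = {p.country: p for p in config.populations}
    records: list[ReferralRecord] = []
    drawn = 0
    max_draws = max(200 * n_retained, 10_000)
    while len(records) < n_retained:
        if drawn >= max_draws:
            raise RuntimeError(
                f"could not reach {n_retained} ascertained subjects in "
                f"{max_draws} draws; variant frequencies are too low"
            )
        drawn += 1
        rec = _draw_subject(drawn, config, populations, rng)
        if config.ascertain and rec.alleles == (WT, WT):
            continue
        records.append(rec)
    records = _apply_missingness(records, config.missingness, rng)
    registry = [p.country for p in config.populations]
    return Cohort.from_records(records, extra_countries=registry), config


# --------------------------------------------------------------------------
# Presets.  26 countries mirroring the mix of North-African, European and
# West/Central-Asian origins typical of an Israeli referral cohort.  The
# paper-like preset plants one geographic cluster per common variant:
# a North-African cluster with a high M694V founder frequency (0.25 — founder
# carrier rates up to ~1 in 4 are documented for such populations), a
# European cluster with elevated V726A, and a West-Asian cluster with
# elevated E148Q, over low shared background frequencies.

NORTH_AFRICA = ("Morocco", "Tunisia", "Libya", "Algeria")
EUROPE = ("Poland", "Romania", "Hungary", "Lebanon")
WEST_ASIA = ("Iran", "India", "Yemen", "Ukraine")
NEUTRAL = (
    "Iraq", "Egypt", "Turkey", "Greece", "Bulgaria", "Syria", "Germany",
    "Russia", "Austria", "France", "Spain", "Italy", "Georgia", "Uzbekistan",
)
ALL_COUNTRIES = NORTH_AFRICA + EUROPE + WEST_ASIA + NEUTRAL

_BACKGROUND = {"M694V": 0.02, "V726A": 0.008, "E148Q": 0.025, "M680I": 0.004, "M694I": 0.002}
_PLANTED = {"M694V": (NORTH_AFRICA, 0.25), "V726A": (EUROPE, 0.10), "E148Q": (WEST_ASIA, 0.12)}


def null_config(n_subjects: int = 2500, seed: int = 0, **overrides) -> SimulationConfig:
    """No-association preset: identical allele frequencies in all 26
    countries, so any apparent origin-variant signal is noise."""
    freqs = {"M694V": 0.06, "V726A": 0.03, "E148Q": 0.05, "M680I": 0.004, "M694I": 0.002}
    pops = tuple(PopulationSpec(c, 1.0, freqs) for c in ALL_COUNTRIES)
    return SimulationConfig(populations=pops, n_subjects=n_subjects, seed=seed, **overrides)


def paper_like_config(n_subjects: int = 7000, seed: int = 0, **overrides) -> SimulationConfig:
    """Planted-cluster preset: each common variant is strongly elevated in
    one group of four countries over a low shared background."""
    pops = []
    for c in ALL_COUNTRIES:
        freqs = dict(_BACKGROUND)
        for variant, (cluster, q) in _PLANTED.items():
            if c in cluster:
                freqs[variant] = q
        pops.append(PopulationSpec(c, 1.0, freqs))
    return SimulationConfig(populations=tuple(pops), n_subjects=n_subjects, seed=seed, **overrides)


def planted_countries(config: SimulationConfig, variant: str, factor: float = 2.0) -> frozenset[str]:
    """Ground-truth cluster for ``variant``: countries whose frequency
    exceeds ``factor`` times the across-country median."""
    qs = {p.country: p.frequencies.get(variant, 0.0) for p in config.populations}
    med = float(np.median(list(qs.values())))
    return frozenset(c for c, q in qs.items() if q > factor * med and q > 0)
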