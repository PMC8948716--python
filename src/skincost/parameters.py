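"""Model inputs: probabilities, unit costs, distributions and conversions.

Every quantity entering a pathway model is a :class:`ParameterSpec`: a point
estimate plus an uncertainty distribution (beta for probabilities, gamma for
costs, or fixed).  A :class:`ParameterSet` is the keyed collection a model is
evaluated against.  This module also holds the small numerical conversions the
models rely on: multi-period-to-annual probability conversion under a constant
hazard, trial-survival-to-annual-transition conversion, method-of-moments
beta/gamma fits, and the AU->NZ unit-cost imputation ratio.
"""

from __future__ import annotations

import enum
import io
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

__all__ = [
    "Country",
    "Cancer",
    "Distribution",
    "Kind",
    "ParameterError",
    "ParameterSpec",
    "ParameterSet",
    "NZ_AU_PRICE_RATIO",
    "multi_period_to_annual_probability",
    "survival_to_annual_transition",
    "fit_beta",
    "fit_gamma",
    "impute_nz_unit_cost",
    "sample_parameter",
    "se_from_quartiles",
]

#: Mean relative price ratio of known AU to NZ unit prices, used to impute
#: NZ unit costs where no NZ source exists.
NZ_AU_PRICE_RATIO = 1.91


class Country(str, enum.Enum):
    AU = "AU"
    NZ = "NZ"


class Cancer(str, enum.Enum):
    MELANOMA = "melanoma"
    KC = "KC"
    SHARED = "shared"


class Distribution(str, enum.Enum):
    BETA = "beta"
    GAMMA = "gamma"
    FIXED = "fixed"


class Kind(str, enum.Enum):
    PROBABILITY = "probability"
    COST = "cost"


class ParameterError(ValueError):
    """Invalid parameter definition or infeasible distribution."""


# ---------------------------------------------------------------------------
# conversions


def multi_period_to_annual_probability(p_multi: float, years: int) -> float:
    """Convert a multi-year probability to an annual one under constant hazard.

    Returns ``1 - (1 - p_multi)**(1/years)``, the annual probability whose
    ``years``-fold compounding recovers ``p_multi`` exactly.  Equivalent to
    converting through the rate ``r = -ln(1 - p_multi) / years`` and back.
    """
    if not 0.0 <= p_multi < 1.0:
        raise ParameterError(f"p_multi must be in [0, 1), got {p_multi!r}")
    if years < 1:
        raise ParameterError(f"years must be >= 1, got {years!r}")
    return 1.0 - (1.0 - p_multi) ** (1.0 / years)


def annual_to_multi_period_probability(p_annual: float, years: int) -> float:
    """Inverse of :func:`multi_period_to_annual_probability`."""
    if not 0.0 <= p_annual < 1.0:
        raise ParameterError(f"p_annual must be in [0, 1), got {p_annual!r}")
    if years < 1:
        raise ParameterError(f"years must be >= 1, got {years!r}")
    return 1.0 - (1.0 - p_annual) ** years


def survival_to_annual_transition(surviving_fraction: float, years: int) -> float:
    """Annual probability of leaving a surviving cohort (e.g. to palliative care).

    Given the fraction still alive after ``years`` (a trial's 4- or 5-year
    overall survival), returns ``1 - surviving_fraction**(1/years)``, the
    constant annual transition probability consistent with that endpoint.
    """
    if not 0.0 < surviving_fraction <= 1.0:
        raise ParameterError(
            f"surviving_fraction must be in (0, 1], got {surviving_fraction!r}"
        )
    if years < 1:
        raise ParameterError(f"years must be >= 1, got {years!r}")
    return 1.0 - surviving_fraction ** (1.0 / years)


def fit_beta(mean: float, se: float) -> tuple[float, float]:
    """Method-of-moments beta fit: (alpha, beta) matching the given mean and SE."""
    if not 0.0 < mean < 1.0:
        raise ParameterError(f"beta mean must be in (0, 1), got {mean!r}")
    if se <= 0.0:
        raise ParameterError(f"se must be positive, got {se!r}")
    var = se * se
    bound = mean * (1.0 - mean)
    if var >= bound:
        raise ParameterError(
            f"infeasible dispersion: se^2={var:.6g} >= mean(1-mean)={bound:.6g}"
        )
    k = bound / var - 1.0
    return mean * k, (1.0 - mean) * k


def fit_gamma(mean: float, se: float) -> tuple[float, float]:
    """Method-of-moments gamma fit: (shape, scale) matching mean and SE."""
    if mean <= 0.0 or se <= 0.0:
        raise ParameterError(f"gamma mean and se must be positive, got {mean!r}, {se!r}")
    shape = (mean / se) ** 2
    scale = se * se / mean
    return shape, scale


def impute_nz_unit_cost(au_cost: float, ratio: float = NZ_AU_PRICE_RATIO) -> float:
    """Impute an NZ unit cost from an AU one via the mean relative price ratio."""
    if au_cost < 0.0:
        raise ParameterError(f"cost must be non-negative, got {au_cost!r}")
    if ratio <= 0.0:
        raise ParameterError(f"ratio must be positive, got {ratio!r}")
    return au_cost * ratio


def se_from_quartiles(
    kind: Kind | str, mean: float, q25: float, q75: float, tol: float = 1e-9
) -> float:
    """Recover a standard error from 25th/75th percentiles of the named family.

    Finds the SE for which the method-of-moments fit (beta for probabilities,
    gamma for costs) at the given mean has interquartile range ``q75 - q25``;
    the root is bracketed around the normal-approximation guess and solved by
    bisection to ``tol``.
    """
    kind = Kind(kind)
    if not q25 < q75:
        raise ParameterError(f"need q25 < q75, got {q25!r}, {q75!r}")
    target_iqr = q75 - q25

    def iqr(se: float) -> float:
        if kind is Kind.PROBABILITY:
            a, b = fit_beta(mean, se)
            d = stats.beta(a, b)
        else:
            shape, scale = fit_gamma(mean, se)
            d = stats.gamma(shape, scale=scale)
        return float(d.ppf(0.75) - d.ppf(0.25))

    # The IQR grows ~1.35 x SE near the normal regime but is not monotone in
    # the SE far from it (very dispersed gammas pile mass near zero), so the
    # bracket is grown outward from the normal-approximation guess.
    guess = target_iqr / 1.349
    if kind is Kind.PROBABILITY:
        se_max = math.sqrt(mean * (1.0 - mean)) * (1.0 - 1e-9)
    else:
        se_max = mean * 100.0
    lo, hi = None, None
    for factor in (0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0):
        se = min(guess * factor, se_max)
        if iqr(se) < target_iqr:
            lo = se
        elif hi is None:
            hi = se
            break
    if lo is None:
        lo = 1e-12
    if hi is None or iqr(hi) < target_iqr:
        raise ParameterError(
            f"quartiles ({q25}, {q75}) infeasible for {kind.value} with mean {mean}"
        )
    return float(optimize.brentq(lambda s: iqr(s) - target_iqr, lo, hi, xtol=tol))


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class ParameterSpec:
    """One model input with its point estimate and uncertainty distribution.

    ``dispersion`` is a standard error in the units of the point estimate;
    alternatively explicit 25th/75th percentiles can be supplied and the SE is
    recovered by numeric inversion assuming the named family.
    """

    name: str
    kind: Kind
    point_estimate: float
    distribution: Distribution = Distribution.FIXED
    se: float | None = None
    q25: float | None = None
    q75: float | None = None
    country: Country = Country.AU
    cancer: Cancer = Cancer.SHARED
    source_tag: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", Kind(self.kind))
        object.__setattr__(self, "distribution", Distribution(self.distribution))
        object.__setattr__(self, "country", Country(self.country))
        object.__setattr__(self, "cancer", Cancer(self.cancer))
        pe = self.point_estimate
        if self.kind is Kind.PROBABILITY:
            if not 0.0 <= pe <= 1.0:
                raise ParameterError(f"{self.name}: probability {pe!r} outside [0, 1]")
            if self.distribution is Distribution.GAMMA:
                raise ParameterError(f"{self.name}: probabilities use beta or fixed")
        else:
            if pe < 0.0:
                raise ParameterError(f"{self.name}: cost {pe!r} must be >= 0")
            if self.distribution is Distribution.BETA:
                raise ParameterError(f"{self.name}: costs use gamma or fixed")
        if self.distribution is not Distribution.FIXED:
            if self.se is None and (self.q25 is None or self.q75 is None):
                raise ParameterError(
                    f"{self.name}: non-fixed spec needs an se or a q25/q75 pair"
                )
            if self.se is not None and self.se <= 0.0:
                raise ParameterError(f"{self.name}: se must be positive")
            # fail fast on infeasible dispersions
            self.fitted_parameters()

    def effective_se(self) -> float | None:
        """The SE, recovering it from quartiles when only those were given."""
        if self.distribution is Distribution.FIXED:
            return self.se
        if self.se is not None:
            return self.se
        return se_from_quartiles(self.kind, self.point_estimate, self.q25, self.q75)

    def fitted_parameters(self) -> tuple[float, float] | None:
        """(alpha, beta) or (shape, scale) of the fitted distribution, None if fixed."""
        if self.distribution is Distribution.FIXED:
            return None
        se = self.effective_se()
        if self.distribution is Distribution.BETA:
            return fit_beta(self.point_estimate, se)
        return fit_gamma(self.point_estimate, se)

    def quantile(self, q: float) -> float:
        """Quantile of the fitted distribution (the point estimate if fixed)."""
        if self.distribution is Distribution.FIXED:
            return self.point_estimate
        a, b = self.fitted_parameters()
        if self.distribution is Distribution.BETA:
            return float(stats.beta(a, b).ppf(q))
        return float(stats.gamma(a, scale=b).ppf(q))

    def sample(self, rng: np.random.Generator) -> float:
        if self.distribution is Distribution.FIXED:
            return self.point_estimate
        a, b = self.fitted_parameters()
        if self.distribution is Distribution.BETA:
            return float(rng.beta(a, b))
        return float(rng.gamma(a, b))


def sample_parameter(spec: ParameterSpec, rng: np.random.Generator) -> float:
    """Draw one value from a spec's fitted distribution (point estimate if fixed)."""
    return spec.sample(rng)


# ---------------------------------------------------------------------------
# sets

_CSV_COLUMNS = [
    "name",
    "country",
    "cancer",
    "type",
    "point_estimate",
    "se",
    "distribution",
    "source_tag",
]


@dataclass
class ParameterSet:
    """A keyed, per-country collection of parameter specs.

    Sampling iterates specs in sorted name order with a single generator, so
    draws are bit-reproducible given (seed, call order).
    """

    country: Country = Country.AU
    currency_year: int = 2021
    entries: dict[str, ParameterSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.country = Country(self.country)

    def add(self, spec: ParameterSpec) -> None:
        if spec.name in self.entries:
            raise ParameterError(f"duplicate parameter name {spec.name!r}")
        self.entries[spec.name] = spec

    def __getitem__(self, name: str) -> ParameterSpec:
        return self.entries[name]

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def __iter__(self) -> Iterator[ParameterSpec]:
        return iter(self.entries.values())

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> set[str]:
        return set(self.entries)

    def point_values(self) -> dict[str, float]:
        return {name: spec.point_estimate for name, spec in self.entries.items()}

    def sample_values(self, rng: np.random.Generator) -> dict[str, float]:
        return {
            name: self.entries[name].sample(rng) for name in sorted(self.entries)
        }

    def replace_value(self, name: str, value: float) -> "ParameterSet":
        """Copy of the set with one point estimate replaced (distribution kept)."""
        spec = self.entries[name]
        out = ParameterSet(self.country, self.currency_year, dict(self.entries))
        out.entries[name] = replace(spec, point_estimate=value)
        return out

    def scaled_costs(self, factor: float, exclude_prefix: str = "cost_scale_") -> "ParameterSet":
        """Copy with every cost parameter (point and SE) scaled by ``factor``.

        Dimensionless per-model scale parameters (``cost_scale_*``) are left
        untouched; they are calibration knobs, not unit costs.
        """
        if factor <= 0.0:
            raise ParameterError(f"scale factor must be positive, got {factor!r}")
        out = ParameterSet(self.country, self.currency_year, {})
        for name, spec in self.entries.items():
            if spec.kind is Kind.COST and not name.startswith(exclude_prefix):
                spec = replace(
                    spec,
                    point_estimate=spec.point_estimate * factor,
                    se=None if spec.se is None else spec.se * factor,
                    q25=None if spec.q25 is None else spec.q25 * factor,
                    q75=None if spec.q75 is None else spec.q75 * factor,
                )
            out.entries[name] = spec
        return out

    # -- serialisation -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in sorted(self.entries):
            s = self.entries[name]
            rows.append(
                {
                    "name": s.name,
                    "country": s.country.value,
                    "cancer": s.cancer.value,
                    "type": s.kind.value,
                    "point_estimate": s.point_estimate,
                    "se": "" if s.se is None else s.se,
                    "distribution": s.distribution.value,
                    "source_tag": s.source_tag,
                }
            )
        return pd.DataFrame(rows, columns=_CSV_COLUMNS)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, currency_year: int = 2021) -> "ParameterSet":
        countries = set(frame["country"])
        country = Country(countries.pop()) if len(countries) == 1 else Country.AU
        out = cls(country=country, currency_year=currency_year)
        for row in frame.to_dict("records"):
            se = row.get("se", "")
            se = None if se in ("", None) or (isinstance(se, float) and math.isnan(se)) else float(se)
            out.add(
                ParameterSpec(
                    name=str(row["name"]),
                    kind=Kind(row["type"]),
                    point_estimate=float(row["point_estimate"]),
                    distribution=Distribution(row["distribution"]),
                    se=se,
                    country=Country(row["country"]),
                    cancer=Cancer(row["cancer"]),
                    source_tag=str(row.get("source_tag", "") or ""),
                )
            )
        return out

    @classmethod
    def from_csv(cls, path, currency_year: int = 2021) -> "ParameterSet":
        return cls.from_frame(pd.read_csv(path, keep_default_na=False), currency_year)

    def to_yaml(self, path=None) -> str | None:
        doc = {
            "country": self.country.value,
            "currency_year": self.currency_year,
            "parameters": {
                name: {
                    "type": s.kind.value,
                    "point_estimate": s.point_estimate,
                    "distribution": s.distribution.value,
                    **({"se": s.se} if s.se is not None else {}),
                    **({"q25": s.q25, "q75": s.q75} if s.q25 is not None else {}),
                    "cancer": s.cancer.value,
                    "source_tag": s.source_tag,
                }
                for name, s in sorted(self.entries.items())
            },
        }
        text = yaml.safe_dump(doc, sort_keys=False)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None

    @classmethod
    def from_yaml(cls, source) -> "ParameterSet":
        if hasattr(source, "read"):
            doc = yaml.safe_load(source)
        elif isinstance(source, str) and "\n" in source:
            doc = yaml.safe_load(io.StringIO(source))
        else:
            with open(source) as fh:
                doc = yaml.safe_load(fh)
        out = cls(
            country=Country(doc.get("country", "AU")),
            currency_year=int(doc.get("currency_year", 2021)),
        )
        for name, entry in doc.get("parameters", {}).items():
            out.add(
                ParameterSpec(
                    name=name,
                    kind=Kind(entry["type"]),
                    point_estimate=float(entry["point_estimate"]),
                    distribution=Distribution(entry.get("distribution", "fixed")),
                    se=entry.get("se"),
                    q25=entry.get("q25"),
                    q75=entry.get("q75"),
                    country=out.country,
                    cancer=Cancer(entry.get("cancer", "shared")),
                    source_tag=str(entry.get("source_tag", "")),
                )
            )
        return out

    @classmethod
    def from_specs(
        cls,
        specs: Iterable[ParameterSpec],
        country: Country | str = Country.AU,
        currency_year: int = 2021,
    ) -> "ParameterSet":
        out = cls(country=Country(country), currency_year=currency_year)
        for spec in specs:
            out.add(spec)
        return out
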