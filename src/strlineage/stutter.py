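"""PCR amplification stutter as a per-cycle slippage Markov chain.

During amplification a polymerase can slip on a tandem repeat, producing a
molecule one unit shorter or longer than its template.  We model a
sequenced read as the end state of a C-step Markov chain on repeat length:
per cycle a molecule loses one unit with probability ``slip_down(unit, L)``,
gains one with ``slip_up(unit, L)``, and is otherwise copied faithfully.
Repeat length 1 is a floor (no further contraction).  Duplex-MIP libraries
behave like 15-20 effective cycles of amplification; the default effective
cycle count is 17, the midpoint of that band.

The per-cycle slip probabilities grow with repeat length (longer repeats
slip more) and depend on the unit class (mono-repeats are noisier than
di-repeats).  A logistic curve in repeat length is used; all parameters are
plain numbers exposed through :class:`SlippageParams` and serializable to
YAML/JSON, since no published constants are assumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .histogram import RepeatHistogram

DEFAULT_CYCLES = 17  # midpoint of the 15-20 effective-cycle band


@dataclass(frozen=True)
class SlippageParams:
    """Logistic per-cycle slippage curve for one repeat-unit class.

    slip_down(L) = p_max / (1 + exp(-(L - midpoint) / scale)), floored to 0
    at L = 1; slip_up(L) = up_ratio * slip_down(L).  ``p_max`` is the
    asymptotic per-cycle contraction probability for very long repeats.
    """

    p_max: float
    midpoint: float
    scale: float
    up_ratio: float = 0.35

    def down(self, length: int) -> float:
        if length <= 1:
            return 0.0
        return self.p_max / (1.0 + np.exp(-(length - self.midpoint) / self.scale))

    def up(self, length: int) -> float:
        return self.up_ratio * self.p_max / (
            1.0 + np.exp(-(length - self.midpoint) / self.scale)
        )


# Defaults per unit-class (keyed by repeat-unit length): mono-repeats slip
# much more readily than di-repeats, longer units barely at all.
DEFAULT_PARAMS: dict[int, SlippageParams] = {
    1: SlippageParams(p_max=0.060, midpoint=10.0, scale=3.0),
    2: SlippageParams(p_max=0.020, midpoint=20.0, scale=5.0),
    3: SlippageParams(p_max=0.008, midpoint=25.0, scale=6.0),
}


def _params_for_unit(params: dict[int, SlippageParams], unit: str) -> SlippageParams:
    k = len(unit)
    if k in params:
        return params[k]
    return params[max(params)]


@dataclass
class StutterModel:
    """Effective cycle count plus per-(unit, length) slip probabilities."""

    cycles: int = DEFAULT_CYCLES
    params: dict[int, SlippageParams] = field(
        default_factory=lambda: dict(DEFAULT_PARAMS)
    )

    def __post_init__(self) -> None:
        if self.cycles < 0:
            raise ValueError("cycles must be >= 0")

    def slip_down(self, unit: str, length: int) -> float:
        return _params_for_unit(self.params, unit).down(length)

    def slip_up(self, unit: str, length: int) -> float:
        return _params_for_unit(self.params, unit).up(length)

    # -- config round-trip -------------------------------------------------
    def to_config(self) -> dict:
        return {
            "cycles": self.cycles,
            "params": {
                str(k): {
                    "p_max": p.p_max,
                    "midpoint": p.midpoint,
                    "scale": p.scale,
                    "up_ratio": p.up_ratio,
                }
                for k, p in self.params.items()
            },
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "StutterModel":
        params = {
            int(k): SlippageParams(**v) for k, v in cfg.get("params", {}).items()
        } or dict(DEFAULT_PARAMS)
        return cls(cycles=int(cfg.get("cycles", DEFAULT_CYCLES)), params=params)


def zero_stutter_model() -> StutterModel:
    """A noise-free model: any cycle count, zero slip probability."""
    return StutterModel(
        cycles=0, params={1: SlippageParams(p_max=0.0, midpoint=10.0, scale=3.0)}
    )


@dataclass(frozen=True)
class StutterDistribution:
    """Repeat-length distribution of reads from a (possibly mixed) genotype."""

    alleles: tuple[int, ...]
    lengths: np.ndarray  # int array, ascending
    probabilities: np.ndarray

    def as_dict(self, eps: float = 0.0) -> dict[int, float]:
        return {
            int(l): float(p)
            for l, p in zip(self.lengths, self.probabilities)
            if p > eps
        }

    def support(self, eps: float = 1e-9) -> tuple[int, int]:
        nz = np.nonzero(self.probabilities > eps)[0]
        return int(self.lengths[nz[0]]), int(self.lengths[nz[-1]])


def _single_cycle_step(
    probs: np.ndarray, down: np.ndarray, up: np.ndarray
) -> np.ndarray:
    """One application of the tridiagonal slippage kernel on lengths 1..K."""
    stay = 1.0 - down - up
    out = probs * stay
    out[:-1] += probs[1:] * down[1:]   # contraction: length i+1 -> i
    out[1:] += probs[:-1] * up[:-1]    # expansion: length i -> i+1
    return out


def predict_histogram(
    model: StutterModel, allele: int, unit: str = "AC"
) -> StutterDistribution:
    """Exact read-length distribution after ``model.cycles`` slippage steps
    starting from a point mass at ``allele`` (dynamic programming)."""
    if allele < 1:
        raise ValueError("allele must be >= 1")
    kmax = allele + model.cycles
    lengths = np.arange(1, kmax + 1)
    down = np.array([model.slip_down(unit, int(l)) for l in lengths])
    up = np.array([model.slip_up(unit, int(l)) for l in lengths])
    down[0] = 0.0  # absorbing floor at one repeat
    if np.any(down + up > 1.0 + 1e-12):
        raise ValueError("slip_down + slip_up exceeds 1 within the support")
    probs = np.zeros(kmax)
    probs[allele - 1] = 1.0
    for _ in range(model.cycles):
        probs = _single_cycle_step(probs, down, up)
    return StutterDistribution(
        alleles=(allele,), lengths=lengths, probabilities=probs
    )


def predict_mixture(
    model: StutterModel,
    allele_a: int,
    allele_b: int,
    fraction_a: float = 0.5,
    unit: str = "AC",
) -> StutterDistribution:
    """Convex mixture of the two single-allele distributions."""
    if not 0.0 <= fraction_a <= 1.0:
        raise ValueError("fraction_a must lie in [0, 1]")
    da = predict_histogram(model, allele_a, unit)
    db = predict_histogram(model, allele_b, unit)
    kmax = max(da.lengths[-1], db.lengths[-1])
    probs = np.zeros(int(kmax))
    probs[: da.probabilities.size] += fraction_a * da.probabilities
    probs[: db.probabilities.size] += (1.0 - fraction_a) * db.probabilities
    return StutterDistribution(
        alleles=tuple(sorted({allele_a, allele_b})),
        lengths=np.arange(1, int(kmax) + 1),
        probabilities=probs,
    )


def sample_histogram(
    model: StutterModel,
    genotype: int | tuple[int, ...],
    n_reads: int,
    rng: np.random.Generator | int | None = None,
    fraction_a: float = 0.5,
    unit: str = "AC",
    cell_id: str = "cell",
    locus_id: str = "locus",
) -> RepeatHistogram:
    """Sample a read histogram from a genotype under the stutter model.

    Each read independently picks a template allele (by ``fraction_a`` for
    heterozygotes) and then undergoes ``model.cycles`` slippage steps; the
    aggregate is therefore a single multinomial draw from the DP-predicted
    mixture distribution, which is how it is implemented.
    """
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    rng = np.random.default_rng(rng)
    alleles = (genotype,) if isinstance(genotype, (int, np.integer)) else tuple(genotype)
    if len(alleles) == 1:
        dist = predict_histogram(model, int(alleles[0]), unit)
    elif len(alleles) == 2:
        dist = predict_mixture(model, int(alleles[0]), int(alleles[1]), fraction_a, unit)
    else:
        raise ValueError("genotype must have one or two alleles")
    counts: dict[int, int] = {}
    if n_reads > 0:
        draws = rng.multinomial(n_reads, dist.probabilities / dist.probabilities.sum())
        counts = {
            int(l): int(c) for l, c in zip(dist.lengths, draws) if c > 0
        }
    return RepeatHistogram(cell_id=cell_id, locus_id=locus_id, counts=counts)
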