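"""Spread metrics: the Spread Quantification Index (SQI) and the classical
Intrinsic Spillover Spread (ISS) of the spillover spreading matrix (SSM).

After compensation, photon-counting error on spillover signal remains as
*spreading* of fluorochrome X's events in every secondary detector B.  SQI
quantifies that spread as the 99th-minus-50th percentile of X's stained
population in B, converted from detector scale units to photon-equivalent
units by a normalisation factor

    NF(Y, B) = P / (YSt_B50 - Un_B50),

where Y is the fluorochrome whose primary detector is B, YSt_B50/Un_B50 are
the stained/unstained medians of Y's own control in B, and P is a fixed
constant (default 9000).  Because both the spread and the normalising
separation scale linearly with detector gain, SQI is independent of
detector voltage/gain and of the instrument's dynamic range.  ISS, by
contrast, is sqrt(sigma_pos^2 - sigma_neg^2) / sqrt(dF) with dF the
stained-minus-unstained median separation in X's *primary* detector, and
inherits a square-root gain dependence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .fcs_io import EventTable, SpilloverMatrix, apply_compensation
from .gating import (
    GatingError,
    PopulationPair,
    gate_single_stain,
    percentile,
    robust_sd,
)

__all__ = [
    "DEFAULT_P",
    "CategoryBins",
    "TEXT_BINS",
    "CAPTION_BINS",
    "SpreadInputs",
    "SQIEntry",
    "ISSEntry",
    "SQIMatrix",
    "SSMMatrix",
    "SingleStainControl",
    "normalization_factor",
    "sqi_value",
    "classify_sqi",
    "percent_occupancy",
    "iss_value",
    "validate_linearity",
    "gate_controls",
    "compute_sqi_matrix",
    "compute_ssm",
    "replicate_cv",
]

#: Default photon-equivalent constant P.
DEFAULT_P = 9000.0

CATEGORIES = ("Green", "Yellow", "Orange", "Red")


class NoSeparationError(ValueError):
    """Reference fluorochrome gives no signal above background in its detector."""


@dataclass(frozen=True)
class CategoryBins:
    """Upper edges of the Green/Yellow/Orange SQI categories (Red is above).

    Two conventions circulate: edges (120, 220, 300) tied to the
    0.5%/1%/1.5% scale-occupancy correspondence, and a variant with edges
    (120, 199, 299).  The former is the default.
    """

    name: str
    green_max: float = 120.0
    yellow_max: float = 220.0
    orange_max: float = 300.0

    def __post_init__(self) -> None:
        if not (0 < self.green_max < self.yellow_max < self.orange_max):
            raise ValueError("category edges must be increasing and positive")

    def classify(self, value: float) -> str:
        if value < 0:
            raise ValueError(f"SQI is non-negative by construction, got {value}")
        if value <= self.green_max:
            return "Green"
        if value <= self.yellow_max:
            return "Yellow"
        if value <= self.orange_max:
            return "Orange"
        return "Red"


TEXT_BINS = CategoryBins("text", 120.0, 220.0, 300.0)
CAPTION_BINS = CategoryBins("caption", 120.0, 199.0, 299.0)

_PRESETS = {"text": TEXT_BINS, "caption": CAPTION_BINS}


def bins_preset(name: str) -> CategoryBins:
    try:
        return _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown bin preset {name!r}; available: {sorted(_PRESETS)}"
        ) from None


# --------------------------------------------------------------------------
# scalar operations
# --------------------------------------------------------------------------


def normalization_factor(yst_b50: float, un_b50: float, p_const: float = DEFAULT_P) -> float:
    """Photon-equivalents per scale unit of detector B: P / (YSt_B50 - Un_B50)."""
    if p_const <= 0:
        raise ValueError("P must be positive")
    sep = yst_b50 - un_b50
    if sep <= 0:
        raise NoSeparationError(
            "reference fluorochrome shows no separation above background "
            f"(YSt_B50 - Un_B50 = {sep:.4g} scale units)"
        )
    return p_const / sep


def sqi_value(x_b99: float, x_b50: float, nf: float) -> float:
    """SQI of fluorochrome X in detector B: (X_B99 - X_B50) x NF."""
    if nf <= 0:
        raise ValueError("normalisation factor must be positive")
    return (x_b99 - x_b50) * nf


def classify_sqi(value: float, bins: CategoryBins = TEXT_BINS) -> str:
    """Green/Yellow/Orange/Red category of an SQI value under the given bins."""
    return bins.classify(value)


def percent_occupancy(yst_b50: float, un_b50: float, dynamic_range: float) -> float:
    """Percentage of detector B's scale units occupied by the reference separation."""
    if dynamic_range <= 0:
        raise ValueError("dynamic_range must be positive")
    return 100.0 * (yst_b50 - un_b50) / dynamic_range


def iss_value(sigma_pos: float, sigma_neg: float, primary_delta_f: float) -> float:
    """Intrinsic spillover spread: sqrt(sigma_pos^2 - sigma_neg^2) / sqrt(dF).

    dF is the stained-minus-unstained median separation in the primary
    detector.  Returns 0 when the stained spread does not exceed the
    unstained spread.
    """
    if primary_delta_f <= 0:
        raise ValueError("primary-detector separation dF must be positive")
    delta_var = max(sigma_pos**2 - sigma_neg**2, 0.0)
    return float(np.sqrt(delta_var / primary_delta_f))


@dataclass(frozen=True)
class SpreadInputs:
    """The per-(X, B, Y) statistics entering SQI, ISS and validity checks."""

    x_b50: float
    x_b99: float
    un_b50: float
    yst_b50: float
    p_const: float = DEFAULT_P
    primary_delta_f: float = float("nan")
    sigma_pos: float = float("nan")
    sigma_neg: float = float("nan")

    def __post_init__(self) -> None:
        if self.p_const <= 0:
            raise ValueError("P must be positive")
        if self.x_b99 < self.x_b50:
            raise ValueError("x_b99 < x_b50 violates percentile monotonicity")


def validate_linearity(
    stats: Mapping[str, float],
    linear_min: float,
    linear_max: float,
) -> tuple[bool, str]:
    """Check that every statistic lies inside the detector's linear range.

    A statistic at or above ``linear_max`` (a pegged percentile) or below
    ``linear_min`` (beyond the electronic-noise floor) invalidates the
    entry.  Returns ``(valid, reason)`` with an empty reason when valid.
    """
    if not linear_min < linear_max:
        raise ValueError("linear_min must be below linear_max")
    for name, value in stats.items():
        if not np.isfinite(value):
            return False, f"{name} is not finite"
        if value >= linear_max:
            return False, f"{name} outside linear range (>= {linear_max:g})"
        if value < linear_min:
            return False, f"{name} outside linear range (< {linear_min:g})"
    return True, ""


# --------------------------------------------------------------------------
# matrix computation
# --------------------------------------------------------------------------


@dataclass
class SingleStainControl:
    """One gated (or gateable) single-stain control acquisition.

    ``pegged_fraction`` optionally records, per channel, the fraction of
    events saturated at the detector's dynamic range in the *raw* (pre-
    compensation) acquisition; any pegging invalidates entries that rely on
    the affected channel, since saturation happens on the measured scale
    where compensation cannot undo it.
    """

    name: str
    primary_channel: str
    table: EventTable
    pair: PopulationPair | None = None
    pegged_fraction: Mapping[str, float] | None = None

    def pegged(self, channel: str) -> float:
        if self.pegged_fraction is None:
            return 0.0
        return float(self.pegged_fraction.get(channel, 0.0))

    def ensure_gated(self, **gate_kwargs) -> PopulationPair:
        if self.pair is None:
            self.pair = gate_single_stain(self.table, self.primary_channel, **gate_kwargs)
        return self.pair

    def stained(self, channel: str) -> np.ndarray:
        return self.table.events[self.ensure_gated().stained_index,
                                 self.table.channel_index(channel)]

    def unstained(self, channel: str) -> np.ndarray:
        return self.table.events[self.ensure_gated().unstained_index,
                                 self.table.channel_index(channel)]


@dataclass(frozen=True)
class SQIEntry:
    source_fluor: str
    secondary_detector: str
    reference_fluor: str
    value: float
    category: str
    percent_occupancy: float
    valid: bool
    invalid_reason: str = ""
    x_b50: float = float("nan")
    x_b99: float = float("nan")
    un_b50: float = float("nan")
    yst_b50: float = float("nan")


@dataclass(frozen=True)
class ISSEntry:
    source_fluor: str
    secondary_detector: str
    value: float
    sigma_pos: float
    sigma_neg: float
    primary_delta_f: float
    valid: bool
    invalid_reason: str = ""


@dataclass
class _EntryGrid:
    entries: list
    p_const: float | None = None

    @property
    def sources(self) -> list[str]:
        seen = dict.fromkeys(e.source_fluor for e in self.entries)
        return list(seen)

    @property
    def detectors(self) -> list[str]:
        seen = dict.fromkeys(e.secondary_detector for e in self.entries)
        return list(seen)

    def get(self, source: str, detector: str, reference: str | None = None):
        for e in self.entries:
            if e.source_fluor == source and e.secondary_detector == detector:
                if reference is None or getattr(e, "reference_fluor", None) == reference:
                    return e
        raise KeyError(f"no entry for ({source!r}, {detector!r})")

    def wide_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(index=self.sources, columns=self.detectors, dtype=float)
        for e in self.entries:
            if np.isnan(frame.at[e.source_fluor, e.secondary_detector]):
                frame.at[e.source_fluor, e.secondary_detector] = e.value
        frame.index.name = "source_fluor"
        return frame


@dataclass
class SQIMatrix(_EntryGrid):
    """Grid of SQI entries, one per (source fluorochrome, secondary detector,
    reference fluorochrome); the diagonal is undefined by construction."""

    bins: CategoryBins = TEXT_BINS

    def long_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source_fluor": [e.source_fluor for e in self.entries],
                "secondary_detector": [e.secondary_detector for e in self.entries],
                "reference_fluor": [e.reference_fluor for e in self.entries],
                "sqi": [e.value for e in self.entries],
                "category": [e.category for e in self.entries],
                "percent_occupancy": [e.percent_occupancy for e in self.entries],
                "valid": [e.valid for e in self.entries],
                "invalid_reason": [e.invalid_reason for e in self.entries],
                "x_b50": [e.x_b50 for e in self.entries],
                "x_b99": [e.x_b99 for e in self.entries],
                "un_b50": [e.un_b50 for e in self.entries],
                "yst_b50": [e.yst_b50 for e in self.entries],
            }
        )

    def merged(self, other: "SQIMatrix") -> "SQIMatrix":
        if other.p_const != self.p_const:
            raise ValueError(
                "refusing to merge SQI matrices computed with different P "
                f"({self.p_const} vs {other.p_const}); SQI scales linearly in P"
            )
        return SQIMatrix(self.entries + other.entries, self.p_const, self.bins)


@dataclass
class SSMMatrix(_EntryGrid):
    """Spillover spreading matrix: one ISS value per (fluorochrome, detector)."""

    def long_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source_fluor": [e.source_fluor for e in self.entries],
                "secondary_detector": [e.secondary_detector for e in self.entries],
                "iss": [e.value for e in self.entries],
                "sigma_pos": [e.sigma_pos for e in self.entries],
                "sigma_neg": [e.sigma_neg for e in self.entries],
                "primary_delta_f": [e.primary_delta_f for e in self.entries],
                "valid": [e.valid for e in self.entries],
                "invalid_reason": [e.invalid_reason for e in self.entries],
            }
        )


def gate_controls(controls: Sequence[SingleStainControl], **gate_kwargs) -> None:
    """Gate every control in place; gating failures propagate."""
    for c in controls:
        c.ensure_gated(**gate_kwargs)


def _linear_bounds(
    meta, noise_floor_frac: float, linear_bounds: Mapping[str, tuple[float, float]] | None
) -> tuple[float, float]:
    if linear_bounds and meta.name in linear_bounds:
        return linear_bounds[meta.name]
    return (-noise_floor_frac * meta.dynamic_range, meta.dynamic_range)


def compute_sqi_matrix(
    controls: Sequence[SingleStainControl],
    p_const: float = DEFAULT_P,
    bins: CategoryBins = TEXT_BINS,
    rsd_method: Literal["mad", "percentile"] = "mad",
    noise_floor_frac: float = 0.01,
    linear_bounds: Mapping[str, tuple[float, float]] | None = None,
    detectors: Sequence[str] | None = None,
    gate_kwargs: Mapping | None = None,
) -> SQIMatrix:
    """Compute the full SQI grid from gated single-stain controls.

    For each ordered pair (X, B) with B not X's primary detector, and for
    each reference fluorochrome Y whose primary detector is B, the entry
    combines X's stained-population 50th/99th percentiles in B with the
    normalisation factor from Y's own control (stained median YSt_B50 and
    blank-bead median Un_B50, both in B).  Detectors with no assigned
    reference fluorochrome yield entries marked invalid.  Entries whose
    statistics leave the configured linear range are flagged invalid with a
    reason, never dropped.
    """
    gate_kwargs = dict(gate_kwargs or {})
    for c in controls:
        c.ensure_gated(**gate_kwargs)

    primary_of = {c.name: c.primary_channel for c in controls}
    refs_for: dict[str, list[SingleStainControl]] = {}
    for c in controls:
        refs_for.setdefault(c.primary_channel, []).append(c)
    detector_list = list(detectors) if detectors is not None else list(
        dict.fromkeys(c.primary_channel for c in controls)
    )

    entries: list[SQIEntry] = []
    for x in sorted(controls, key=lambda c: c.name):
        for det in detector_list:
            if det == x.primary_channel:
                continue
            references = refs_for.get(det, [])
            if not references:
                entries.append(
                    SQIEntry(x.name, det, "", float("nan"), "", float("nan"),
                             False, "no reference fluorochrome")
                )
                continue
            meta_b = x.table.channel(det)
            lo_b, hi_b = _linear_bounds(meta_b, noise_floor_frac, linear_bounds)
            spill_vals = x.stained(det)
            x_b50 = percentile(spill_vals, 50.0)
            x_b99 = percentile(spill_vals, 99.0)
            prim_meta = x.table.channel(x.primary_channel)
            lo_p, hi_p = _linear_bounds(prim_meta, noise_floor_frac, linear_bounds)
            x_p_pos = percentile(x.stained(x.primary_channel), 50.0)
            x_p_neg = percentile(x.unstained(x.primary_channel), 50.0)

            for y in sorted(references, key=lambda c: c.name):
                un_b50 = percentile(y.unstained(det), 50.0)
                yst_b50 = percentile(y.stained(det), 50.0)
                try:
                    nf = normalization_factor(yst_b50, un_b50, p_const)
                except NoSeparationError as exc:
                    entries.append(
                        SQIEntry(x.name, det, y.name, float("nan"), "",
                                 float("nan"), False, str(exc),
                                 x_b50, x_b99, un_b50, yst_b50)
                    )
                    continue
                value = sqi_value(x_b99, x_b50, nf)
                occupancy = percent_occupancy(yst_b50, un_b50, meta_b.dynamic_range)
                valid, reason = validate_linearity(
                    {
                        "x_b99": x_b99,
                        "x_b50": x_b50,
                        "yst_b50": yst_b50,
                        "un_b50": un_b50,
                    },
                    lo_b,
                    hi_b,
                )
                if valid:
                    valid, reason = validate_linearity(
                        {"primary stained median": x_p_pos,
                         "primary unstained median": x_p_neg},
                        lo_p,
                        hi_p,
                    )
                if valid:
                    for ctrl, chans in ((x, (det, x.primary_channel)),
                                        (y, (det,))):
                        for ch in chans:
                            if ctrl.pegged(ch) > 0:
                                valid = False
                                reason = (
                                    f"pegged events in {ctrl.name} control, "
                                    f"channel {ch} (fraction "
                                    f"{ctrl.pegged(ch):.2g})"
                                )
                                break
                        if not valid:
                            break
                entries.append(
                    SQIEntry(
                        x.name, det, y.name, value, bins.classify(max(value, 0.0)),
                        occupancy, valid, reason, x_b50, x_b99, un_b50, yst_b50,
                    )
                )
    return SQIMatrix(entries, p_const, bins)


def compute_ssm(
    controls: Sequence[SingleStainControl],
    rsd_method: Literal["mad", "percentile"] = "mad",
    detectors: Sequence[str] | None = None,
    gate_kwargs: Mapping | None = None,
) -> SSMMatrix:
    """Compute the classical spillover spreading matrix (ISS per cell).

    sigma_pos/sigma_neg are robust SDs of X's stained/unstained events in
    the secondary detector; dF is X's stained-minus-unstained median
    separation in its primary detector.
    """
    gate_kwargs = dict(gate_kwargs or {})
    for c in controls:
        c.ensure_gated(**gate_kwargs)
    detector_list = list(detectors) if detectors is not None else list(
        dict.fromkeys(c.primary_channel for c in controls)
    )
    entries: list[ISSEntry] = []
    for x in sorted(controls, key=lambda c: c.name):
        delta_f = percentile(x.stained(x.primary_channel), 50.0) - percentile(
            x.unstained(x.primary_channel), 50.0
        )
        for det in detector_list:
            if det == x.primary_channel:
                continue
            s_pos = robust_sd(x.stained(det), method=rsd_method)
            s_neg = robust_sd(x.unstained(det), method=rsd_method)
            if delta_f <= 0:
                entries.append(
                    ISSEntry(x.name, det, float("nan"), s_pos, s_neg, delta_f,
                             False, "non-positive primary separation dF")
                )
                continue
            entries.append(
                ISSEntry(x.name, det, iss_value(s_pos, s_neg, delta_f),
                         s_pos, s_neg, delta_f, True)
            )
    return SSMMatrix(entries)


def replicate_cv(matrices: Sequence[SQIMatrix]) -> pd.DataFrame:
    """Coefficient of variation (%) of SQI across replicate acquisitions.

    Entries are matched on (source, detector, reference); all matrices must
    share the same P.
    """
    if len(matrices) < 2:
        raise ValueError("need at least 2 replicate matrices")
    p0 = matrices[0].p_const
    if any(m.p_const != p0 for m in matrices):
        raise ValueError("replicate matrices must share the same P")
    keyed: dict[tuple[str, str, str], list[float]] = {}
    for m in matrices:
        for e in m.entries:
            if e.valid:
                keyed.setdefault(
                    (e.source_fluor, e.secondary_detector, e.reference_fluor), []
                ).append(e.value)
    rows = []
    for (src, det, ref), vals in sorted(keyed.items()):
        if len(vals) < 2:
            continue
        arr = np.asarray(vals)
        rows.append(
            {
                "source_fluor": src,
                "secondary_detector": det,
                "reference_fluor": ref,
                "n_replicates": len(vals),
                "mean_sqi": arr.mean(),
                "cv_percent": 100.0 * arr.std(ddof=1) / arr.mean(),
            }
        )
    return pd.DataFrame(rows)
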