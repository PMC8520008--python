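"""Synthetic single-stain bead controls from a photon-counting detector model.

The generative cascade per event and detector B is the minimal model
consistent with the two linearity assumptions underlying the SQI
normalisation (photon flux independent of detector settings; strictly
linear photon-to-photoelectron-to-scale-unit conversion):

    brightness   b  ~ LogNormal(mean lam_pos, CV)      [stained beads; 0 for blanks]
    photons      N  ~ Poisson(s[X][B] * b + lam_auto[B])
    photoelectrons  ~ Binomial(N, q[B])
    intensity       = gain[B] * (pe + nu * sqrt(pe) * Z) + Normal(0, electronic_noise[B])

clipped to the detector's dynamic range (clipped events are flagged
"pegged").  The ``nu`` term is single-photoelectron gain dispersion: each
photoelectron's amplified charge varies (secondary-emission statistics),
with per-pe CV ``nu``, so the total charge for ``pe`` photoelectrons has
SD ``gain * nu * sqrt(pe)``.  It is mean-zero and proportional to gain,
so it leaves every gain-scaling property intact while removing the
unphysical lattice (multiples of ``gain``) that a noiseless pe-to-scale
conversion would imprint on low-count channels.  Gain enters the output
only as a multiplier, so spreading and reference separations scale
together -- the property SQI exploits.

Truth labels (stained vs blank) travel in a side channel of the returned
object, never inside the event table the analysis path reads, so gating is
exercised blind.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .fcs_io import (
    ChannelMeta,
    ControlManifest,
    EventTable,
    ManifestEntry,
    SpilloverMatrix,
    write_fcs,
)

__all__ = [
    "FluorSpec",
    "SimConfig",
    "SimulatedControl",
    "SimOutput",
    "simulate_control",
    "simulate_panel",
    "draw_brightness",
    "gain_scenario",
    "scale_unit_spillover",
    "reference_config",
    "make_reference_fixtures",
    "write_sim_output",
    "REFERENCE_SPILLOVER",
]

DEFAULT_AUTOFLUOR = 30.0  # photons per event per detector
DEFAULT_GAIN = 12.0  # scale units per photoelectron (positives near 110k/262k)
DEFAULT_QE = 1.0
DEFAULT_NOISE_SD = 3.0  # scale units; noise floor well below photon noise
DEFAULT_DYNAMIC_RANGE = 262144.0
DEFAULT_BRIGHTNESS_CV = 0.08
DEFAULT_PE_DISPERSION = 0.4  # single-photoelectron gain CV (PMT cascade statistics)


@dataclass(frozen=True)
class FluorSpec:
    """One fluorochrome: its primary detector and mean photon yield there."""

    name: str
    primary_detector: str
    lam_pos: float
    brightness_cv: float = DEFAULT_BRIGHTNESS_CV

    def __post_init__(self) -> None:
        if self.lam_pos <= 0:
            raise ValueError("lam_pos must be positive")
        if self.brightness_cv < 0:
            raise ValueError("brightness_cv must be non-negative")


def _as_detector_map(value, detectors: Sequence[str], what: str) -> dict[str, float]:
    if isinstance(value, Mapping):
        out = {d: float(value.get(d, np.nan)) for d in detectors}
        missing = [d for d, v in out.items() if np.isnan(v)]
        if missing:
            raise ValueError(f"{what} missing for detectors {missing}")
    else:
        out = {d: float(value) for d in detectors}
    if any(v < 0 for v in out.values()):
        raise ValueError(f"{what} must be non-negative")
    return out


@dataclass
class SimConfig:
    """Parameters of the photon-counting control simulator.

    ``spillover`` holds photon fractions s[X][B] in [0, 1) with the
    convention s[X][primary(X)] = 1; per-detector scalars are broadcast.
    """

    fluorochromes: list[FluorSpec]
    spillover: dict[str, dict[str, float]]
    n_events: int = 35_000
    stained_fraction: float = 0.6
    autofluorescence: dict[str, float] | float = DEFAULT_AUTOFLUOR
    gains: dict[str, float] | float = DEFAULT_GAIN
    quantum_efficiency: dict[str, float] | float = DEFAULT_QE
    electronic_noise_sd: dict[str, float] | float = DEFAULT_NOISE_SD
    dynamic_range: dict[str, float] | float = DEFAULT_DYNAMIC_RANGE
    pe_gain_dispersion: float = DEFAULT_PE_DISPERSION
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.fluorochromes:
            raise ValueError("at least one fluorochrome is required")
        names = [f.name for f in self.fluorochromes]
        if len(set(names)) != len(names):
            raise ValueError("fluorochrome names must be unique")
        if not 0.0 < self.stained_fraction < 1.0:
            raise ValueError("stained_fraction must lie in (0, 1)")
        if self.n_events < 2:
            raise ValueError("n_events must be at least 2")
        dets = self.detectors
        self.autofluorescence = _as_detector_map(self.autofluorescence, dets, "autofluorescence")
        self.gains = _as_detector_map(self.gains, dets, "gains")
        self.quantum_efficiency = _as_detector_map(self.quantum_efficiency, dets, "quantum_efficiency")
        self.electronic_noise_sd = _as_detector_map(self.electronic_noise_sd, dets, "electronic_noise_sd")
        self.dynamic_range = _as_detector_map(self.dynamic_range, dets, "dynamic_range")
        if any(not 0.0 < q <= 1.0 for q in self.quantum_efficiency.values()):
            raise ValueError("quantum efficiencies must lie in (0, 1]")
        if self.pe_gain_dispersion < 0:
            raise ValueError("pe_gain_dispersion must be non-negative")
        for f in self.fluorochromes:
            row = self.spillover.get(f.name)
            if row is None:
                raise ValueError(f"no spillover row for fluorochrome {f.name!r}")
            for d in dets:
                s = row.get(d, 1.0 if d == f.primary_detector else 0.0)
                if d == f.primary_detector:
                    if s != 1.0:
                        raise ValueError(
                            f"s[{f.name}][{d}] must be 1 (primary-detector convention)"
                        )
                elif not 0.0 <= s < 1.0:
                    raise ValueError(f"s[{f.name}][{d}] = {s} outside [0, 1)")

    @property
    def detectors(self) -> list[str]:
        # unique channels in first-appearance order (several fluorochromes
        # may share a primary detector, e.g. alternative reference dyes)
        return list(dict.fromkeys(f.primary_detector for f in self.fluorochromes))

    def fluor(self, name: str) -> FluorSpec:
        for f in self.fluorochromes:
            if f.name == name:
                return f
        raise KeyError(f"no fluorochrome named {name!r}")

    def spill_fraction(self, fluor: str, detector: str) -> float:
        spec = self.fluor(fluor)
        if detector == spec.primary_detector:
            return 1.0
        return float(self.spillover[fluor].get(detector, 0.0))

    @property
    def n_stained(self) -> int:
        return int(round(self.stained_fraction * self.n_events))


@dataclass
class SimulatedControl:
    """One simulated acquisition plus its analysis-invisible truth labels."""

    fluor: str
    table: EventTable  # uncompensated scale-unit intensities
    truth_stained: np.ndarray  # bool per event; partitions events
    pegged: np.ndarray  # bool per event, any channel clipped at range


@dataclass
class SimOutput:
    controls: dict[str, SimulatedControl]
    spillover: SpilloverMatrix  # scale-unit coefficients for compensation
    config: SimConfig


def scale_unit_spillover(config: SimConfig) -> SpilloverMatrix:
    """Spillover coefficients on the observed (scale-unit) axis.

    Row i is the fluorochrome whose primary detector is channel i:
    S[i][j] = s[X_i][B_j] * (g_j q_j) / (g_i q_i), unit diagonal.
    """
    dets = config.detectors
    n = len(dets)
    coeff = np.eye(n)
    for i, d_i in enumerate(dets):
        # row = first fluorochrome whose primary detector is this channel
        f = next(f for f in config.fluorochromes if f.primary_detector == d_i)
        gi = config.gains[d_i] * config.quantum_efficiency[d_i]
        for j, d_j in enumerate(dets):
            if d_j == d_i:
                continue
            gj = config.gains[d_j] * config.quantum_efficiency[d_j]
            coeff[i, j] = config.spill_fraction(f.name, d_j) * gj / gi
    return SpilloverMatrix(list(dets), coeff)


def draw_brightness(
    config: SimConfig, seed: int | np.random.SeedSequence | None = None
) -> dict[str, np.ndarray]:
    """Pre-draw per-bead brightness for every fluorochrome's stained beads.

    Brightness is a property of the bead preparation; sharing these draws
    across acquisitions models re-running the same tube under different
    detector settings.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(
        config.seed if seed is None else seed
    )
    out: dict[str, np.ndarray] = {}
    for f, child in zip(config.fluorochromes, ss.spawn(len(config.fluorochromes))):
        rng = np.random.default_rng(child)
        if f.brightness_cv == 0:
            out[f.name] = np.full(config.n_stained, f.lam_pos)
        else:
            sig2 = np.log1p(f.brightness_cv**2)
            mu = np.log(f.lam_pos) - sig2 / 2.0
            out[f.name] = rng.lognormal(mu, np.sqrt(sig2), size=config.n_stained)
    return out


def simulate_control(
    config: SimConfig,
    fluor: str,
    rng: int | np.random.Generator | None = None,
    brightness: np.ndarray | None = None,
) -> SimulatedControl:
    """Simulate one single-stain control acquisition (stained + blank beads).

    ``brightness`` optionally supplies pre-drawn stained-bead photon yields
    (see :func:`draw_brightness`); shot noise, detector noise and event
    order are always drawn fresh from ``rng``.
    """
    spec = config.fluor(fluor)
    if rng is None or isinstance(rng, int):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    n = config.n_events
    n_stained = config.n_stained
    if brightness is None:
        if spec.brightness_cv == 0:
            brightness = np.full(n_stained, spec.lam_pos)
        else:
            sig2 = np.log1p(spec.brightness_cv**2)
            mu = np.log(spec.lam_pos) - sig2 / 2.0
            brightness = rng.lognormal(mu, np.sqrt(sig2), size=n_stained)
    elif len(brightness) != n_stained:
        raise ValueError(
            f"brightness has {len(brightness)} entries for {n_stained} stained beads"
        )

    b_full = np.zeros(n)
    b_full[:n_stained] = brightness  # blanks carry zero fluorochrome signal
    dets = config.detectors
    events = np.empty((n, len(dets)))
    pegged = np.zeros(n, dtype=bool)
    channels = []
    for j, d in enumerate(dets):
        s = config.spill_fraction(fluor, d)
        lam_auto = config.autofluorescence[d]
        g = config.gains[d]
        q = config.quantum_efficiency[d]
        dr = config.dynamic_range[d]
        expected_top = g * q * (s * spec.lam_pos + lam_auto)
        if expected_top >= dr:
            warnings.warn(
                f"expected stained intensity {expected_top:.3g} in detector {d} "
                f"meets or exceeds the dynamic range {dr:.3g}; events will peg",
                UserWarning,
                stacklevel=2,
            )
        photons = rng.poisson(s * b_full + lam_auto)
        pe = photons if q >= 1.0 else rng.binomial(photons, q)
        intensity = g * pe.astype(float)
        nu = config.pe_gain_dispersion
        if nu > 0:  # per-photoelectron amplification spread, scales with gain
            intensity = intensity + g * nu * np.sqrt(pe) * rng.standard_normal(n)
        noise_sd = config.electronic_noise_sd[d]
        if noise_sd > 0:
            intensity = intensity + rng.normal(0.0, noise_sd, size=n)
        over = intensity > dr
        pegged |= over
        events[:, j] = np.where(over, dr, intensity)
        channels.append(ChannelMeta(d, detector_label=d, gain=g, dynamic_range=dr))

    order = rng.permutation(n)  # interleave stained and blank beads
    truth = np.zeros(n, dtype=bool)
    truth[:n_stained] = True
    return SimulatedControl(
        fluor=fluor,
        table=EventTable(channels, events[order], compensated=False),
        truth_stained=truth[order],
        pegged=pegged[order],
    )


def simulate_panel(
    config: SimConfig,
    seed: int | None = None,
    brightness: Mapping[str, np.ndarray] | None = None,
) -> SimOutput:
    """Simulate one control acquisition per fluorochrome in the panel."""
    ss = np.random.SeedSequence(config.seed if seed is None else seed)
    controls: dict[str, SimulatedControl] = {}
    for f, child in zip(config.fluorochromes, ss.spawn(len(config.fluorochromes))):
        controls[f.name] = simulate_control(
            config,
            f.name,
            rng=np.random.default_rng(child),
            brightness=None if brightness is None else brightness[f.name],
        )
    return SimOutput(controls, scale_unit_spillover(config), config)


def gain_scenario(
    base: SimConfig, scale: Mapping[str, float] | float
) -> SimConfig:
    """A config identical to ``base`` except detector gains multiplied.

    Photon rates are untouched: changing amplification does not change the
    light reaching the detector.
    """
    if isinstance(scale, Mapping):
        factors = {d: float(scale.get(d, 1.0)) for d in base.detectors}
    else:
        factors = {d: float(scale) for d in base.detectors}
    if any(v <= 0 for v in factors.values()):
        raise ValueError("gain factors must be positive")
    new_gains = {d: base.gains[d] * factors[d] for d in base.detectors}
    return replace(
        base,
        gains=new_gains,
        autofluorescence=dict(base.autofluorescence),
        quantum_efficiency=dict(base.quantum_efficiency),
        electronic_noise_sd=dict(base.electronic_noise_sd),
        dynamic_range=dict(base.dynamic_range),
    )


# --------------------------------------------------------------------------
# reference fixture panel
# --------------------------------------------------------------------------

#: Photon-fraction spillover of the six-fluorochrome reference panel,
#: spanning s = 0.001 (spectrally distant) to s = 0.3 (heavily overlapping).
REFERENCE_SPILLOVER: dict[str, dict[str, float]] = {
    "BB700":    {"B695": 1.0, "V605": 0.002, "V710": 0.08,  "YG610": 0.01,  "YG670": 0.15,  "R730": 0.05},
    "BV605":    {"B695": 0.01, "V605": 1.0,  "V710": 0.12,  "YG610": 0.03,  "YG670": 0.005, "R730": 0.002},
    "BV711":    {"B695": 0.06, "V605": 0.04, "V710": 1.0,   "YG610": 0.002, "YG670": 0.02,  "R730": 0.10},
    "PE-CF594": {"B695": 0.005, "V605": 0.20, "V710": 0.01, "YG610": 1.0,   "YG670": 0.09,  "R730": 0.003},
    "PE-Cy5":   {"B695": 0.03, "V605": 0.001, "V710": 0.05, "YG610": 0.07,  "YG670": 1.0,   "R730": 0.30},
    "APC-R700": {"B695": 0.002, "V605": 0.003, "V710": 0.15, "YG610": 0.001, "YG670": 0.04, "R730": 1.0},
}

_REFERENCE_FLUORS = [
    #            name        detector  photons  (brightness varies as real panels do)
    FluorSpec("BB700", "B695", 9000.0),
    FluorSpec("BV605", "V605", 12000.0),
    FluorSpec("BV711", "V710", 6000.0),
    FluorSpec("PE-CF594", "YG610", 15000.0),
    FluorSpec("PE-Cy5", "YG670", 9000.0),
    FluorSpec("APC-R700", "R730", 3000.0),  # dim reference for its detector
]


def reference_config(n_events: int = 35_000, seed: int = 0) -> SimConfig:
    """The canonical six-control panel used throughout the test suite."""
    return SimConfig(
        fluorochromes=list(_REFERENCE_FLUORS),
        spillover={k: dict(v) for k, v in REFERENCE_SPILLOVER.items()},
        n_events=n_events,
        seed=seed,
    )


def make_reference_fixtures(seed: int = 0, n_events: int = 35_000) -> SimOutput:
    """Deterministic reference fixture set: same seed, byte-identical output."""
    return simulate_panel(reference_config(n_events=n_events, seed=seed))


def write_sim_output(out: SimOutput, outdir: str | Path) -> Path:
    """Write FCS controls, truth sidecars, spillover CSV and manifest CSV.

    Returns the manifest path.  FCS files carry the scale-unit spillover
    matrix in the $SPILLOVER keyword, so they feed the compute pipeline
    exactly like vendor files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for f in out.config.fluorochromes:
        ctrl = out.controls[f.name]
        stem = f.name.replace("/", "_").replace(" ", "_")
        fcs_path = outdir / f"{stem}.fcs"
        write_fcs(ctrl.table, fcs_path, spillover=out.spillover,
                  extra_keywords={"SQIFLOW_SEED": str(out.config.seed)})
        np.savetxt(
            outdir / f"{stem}.truth.csv",
            ctrl.truth_stained.astype(int),
            fmt="%d",
            header="stained",
            comments="",
        )
        entries.append(ManifestEntry(f.name, f.primary_detector, fcs_path.name, False))
    out.spillover.to_csv(outdir / "spillover.csv")
    manifest = ControlManifest(entries)
    manifest_path = outdir / "manifest.csv"
    manifest.to_csv(manifest_path)
    return manifest_path
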