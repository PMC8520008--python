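# Methods

## Spread model and statistics

Compensation is linear unmixing: an observed event row `o` relates to the
true per-fluorochrome signal `t` through the spillover matrix `S` (rows =
source fluorochromes, columns = detectors, unit diagonal, off-diagonal in
[0, 1)) as `o = t·S`; compensating solves the system per event. Means are
corrected exactly; the Poisson counting error of the spillover photons is
not, and remains as spreading of the compensated data in every secondary
detector. Negative compensated values are preserved throughout — the
method's statistics (medians of near-zero populations, robust SDs) depend
on them.

**SQI.** For source fluorochrome X, secondary detector B and reference
fluorochrome Y (the fluorochrome assigned to B):

    NF_Y^B  = P / (YSt_B50 − Un_B50)
    SQI_X^B = (X_B99 − X_B50) · NF_Y^B

`X_B50`, `X_B99`: 50th/99th percentiles of X's gated stained population in
B. `YSt_B50`, `Un_B50`: medians of Y's gated stained and blank populations
in Y's own control file, both read in B; subtracting the blank median
cancels per-detector autofluorescence offsets. P (default 9000,
configurable) is the photon-equivalent constant that fixes the scale; SQI
is linear in P, so matrices record their P and refuse to merge across
different values. The index rests on two assumptions: (1) changing a
detector's gain does not change the photons reaching it, and (2) the
photon → photoelectron → scale-unit chain is linear. Under these, spread
and reference separation scale together and the gain cancels; the same
cancellation makes the index independent of the instrument's dynamic
range. It fails, by design, outside the detector's linear range and when
the spread is not clearly above the electronic-noise floor.

**ISS.** Each cell of the classical spillover spreading matrix is
`sqrt(max(σ₊² − σ₋², 0)) / sqrt(ΔF)`, with σ₊/σ₋ the robust SDs of X's
stained/blank populations in B and ΔF the stained-minus-blank median
separation in X's *primary* detector. ΔF scales with the primary gain and
σ with the secondary gain, so ISS scales as c·√(1/c′) under secondary/
primary gain factors c, c′ — the gain subjectivity SQI removes. ISS is
computed for comparison and for instrument-tracking use cases.

**Categories.** Default bin edges 120/220/300 (Green/Yellow/Orange/Red);
these are the edges tied to the 0.5%/1%/1.5% scale-occupancy
correspondence. A variant convention with edges 120/199/299 circulates in
tabulated material and is available as the `caption` preset; custom edges
are accepted. Percent occupancy, `100·(YSt_B50 − Un_B50)/dynamic_range`,
is reported alongside every entry but never used to enforce a category —
no formula links the two scales.

**Validity.** An entry is flagged invalid (with a reason, never dropped)
when any of its statistics — X's percentiles in B, Y's medians in B, X's
primary medians — leaves the channel's linear range `[−noise_floor,
dynamic_range)` (noise floor default: 1% of the dynamic range,
configurable per channel), when the reference shows no separation
(`YSt_B50 ≤ Un_B50`), when a detector has no assigned reference
fluorochrome, or when the raw acquisition contains events pegged at the
dynamic range in an involved channel. Pegging is assessed on the raw
(pre-compensation) scale because saturation happens there; compensated
statistics can sit innocently below the range while the underlying signal
clipped.

## Gating

Each single-stain control contains blank and stained beads. The two
populations are separated on the primary-detector axis by an EM fit of a
two-component univariate normal mixture, applied by default to the
*absolute values* of the compensated intensities — mirroring the
established analysis workflow for these controls. Folding the negative
tail of the blank population biases its fitted mean/SD slightly upward;
because the workflow is defined this way we keep it as the default and
expose `use_abs=False` for sensitivity analysis, without guessing which
behaviour is "intended". With the default simulator settings the blank
population is almost entirely positive and the folding is a no-op (the
test suite checks signed and folded gating agree there).

EM details: initialised by splitting at the overall median (each half
seeds one component, weights 0.5/0.5), plus 3 restarts with
normally-perturbed means (SD = half the overall SD); best log-likelihood
wins. Convergence when successive log-likelihoods differ by < 1e-6;
max 500 iterations, non-convergence returns the fit with a warning rather
than failing the run. Component SDs are floored at 1e-6 of the data range
to prevent collapse. The per-iteration log-likelihood history is kept on
the fit object; a property test asserts it is non-decreasing.

Each population's gate is the first-to-third-quartile interval of its
fitted normal, `mean ± Φ⁻¹(0.75)·sd` with the exact constant
0.6744897501960817, so a well-fitted gate retains the central 50% of its
component. Events eligible for both gates go to the component with the
smaller standardised distance `|x − mean|/sd`. Two failure checks guard
the fit: (1) the fitted mixture must show a genuine density trough between
the component means (minimum density between means below half the smaller
of the densities at the means) — a unimodal sample split by EM into two
overlapping half-populations fails this; (2) the two quartile gates must
not overlap by more than half the narrower gate. At least 1000 events are
required; below 35,000 (the recommended minimum for a stable 99th
percentile) a warning is emitted.

**Order statistics.** Percentiles use linear interpolation between closest
ranks (type 7). The robust SD is 1.4826·MAD by default (the consistent
estimator of σ for normal data); the percentile convention
`(P84.13 − P15.87)/2` is available as an option. At the prescribed event
counts the differences between percentile conventions are far below every
tolerance used here. The exact conventions in force are logged in every
run header so published numbers are attributable to them.

## The simulator

The generative model per event and detector B is the minimal cascade
consistent with the two linearity assumptions:

| stage | model | default |
|---|---|---|
| bead brightness (stained) | LogNormal, mean λ_pos, CV | λ_pos 3,000–15,000 photons by fluorochrome; CV 8% |
| photons | Poisson(s[X][B]·b + λ_auto[B]) | spillover fractions s per config; λ_auto 30 photons |
| photoelectrons | Binomial(photons, q[B]) | q = 1 |
| amplification | g·pe + g·ν·√pe·Z | g = 12 scale units/pe; ν = 0.4 |
| electronics | + Normal(0, σ_e), clip at dynamic range | σ_e = 3 scale units; range 262,144 |

Blank beads carry b = 0 (autofluorescence only). The stained fraction is
0.6 of `n_events` (default 35,000, the recommended minimum acquisition),
split deterministically and interleaved by a seeded permutation. Truth
labels and pegged-event flags travel outside the event table so the
analysis path is exercised blind. The scale-unit spillover matrix used for
compensation follows from the photon fractions and per-detector gains;
simulated FCS files embed it in the standard spillover keyword so they
feed the CLI exactly like vendor files.

Parameter rationale. λ_pos values span dim to bright conjugates
(3,000–15,000 photons) so that, with P = 9000, reference separations and
SQI entries cover all four categories as real panels do; the dim
fluorochrome doubles as the "dim reference" scenario in which the same
physical spread produces a larger SQI. λ_auto = 30 photons gives blank
populations a realistic width and keeps low-count channels approximately
normal for the mixture fit; the resulting baseline for zero-spillover
entries is ≈ 2.4·√(λ_auto(1+ν²)) ≈ 15 SQI units of pure counting error.
The bead-brightness CV of 8% reproduces realistic positive-population
widths. ν = 0.4 is single-photoelectron gain dispersion
(secondary-emission statistics of a PMT): mean-zero and proportional to
gain, it leaves every gain-scaling property exactly intact while removing
the artificial lattice (intensities at multiples of g) that a noiseless
pe→scale conversion would imprint on low-count channels — a lattice on
which the MAD-based robust SD is unstable and which real data does not
show. The electronic noise floor, constant in scale units, is the one
deliberate violation of strict linearity; at 3 scale units (0.25 pe) it
stays well below photon statistics for every entry, matching the method's
own validity precondition that the spread lie outside the detector noise.
A noisier floor is configurable precisely to study that failure mode.

What the simulator does not model: tandem-dye degradation and lot
variation, laser-power effects, scatter parameters and doublets, and
APD/SiPM-specific noise physics. Passing tests therefore demonstrate the
statistical machinery and the invariance algebra under the stated
assumptions, not robustness to those instrument pathologies; on real data
the compensation quality and the linearity checks carry the corresponding
burden.

## Simulation experiments and problem sizes

Gain- and dynamic-range-invariance checks compare full re-acquisitions of
the *same* simulated bead preparation: bead-brightness draws are shared
across scenarios (beads are physical objects; the experiments they mirror
re-run the same tube), while photon shot noise, detector noise and event
order are redrawn from distinct seeds per acquisition. These checks run at
250,000 events per control so that the sampling error of the 99th
percentile of a quartile-gated population (~0.8% per acquisition, ~1.1%
between two) sits well inside the 3% assertion bands. Reproducibility and
gating-recovery checks use the prescribed 35,000-event acquisitions with
fully independent replicates; between-replicate CV of SQI measures ~1–2%
there.

For ISS, the closed-form √-gain factor is asserted per entry wherever the
stained spread clearly exceeds background (σ₊² ≥ 2σ₋²); closer to
background the statistic `sqrt(σ₊² − σ₋²)` becomes sampling-limited — its
relative error diverges as σ₊ → σ₋ — so for those entries only the
panel-wide median ratio is asserted. This is a property of the ISS
estimator itself, and one more reason a percentile-based index is the
sturdier readout near zero spread.

## Known limitations

* FCS support covers list-mode 3.0/3.1 with float/double/uniform-integer
  data, the standard gain/log keywords and the common spillover keyword
  dialects; FCS 2.0 and analysis segments are out of scope, as are
  logicle/biexponential display transforms (all statistics are computed on
  the linear scale).
* One compensation matrix per run: when several fluorochromes share a
  primary detector, the channel-level matrix uses the first one's
  profile — exact when the alternatives have matching spill profiles, an
  approximation otherwise.
* SQI is a point estimate; replicate CV is reported when replicate
  controls are supplied, but no confidence machinery is attached.
* The index is not a voltage/gain optimisation tool and the package
  deliberately offers nothing in that direction.
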