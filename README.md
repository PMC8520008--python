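# sqiflow

Gain- and dynamic-range-independent quantification of spillover spreading
in flow cytometry, for panel designers and core-facility operators.

## The problem

In conventional cytometers each fluorochrome has a dedicated (primary)
detector, but its emission also reaches other (secondary) detectors —
*spillover*. Compensation removes the spillover signal's mean, but the
photon-counting error on that signal survives as *spreading* of the
compensated data, which masks dim populations. The established metric, the
spillover spreading matrix (SSM) with its per-cell intrinsic spillover
spread (ISS), depends on detector voltage/gain: lowering voltages lowers
ISS without reducing the physical spread, which invites counterproductive
"optimization". `sqiflow` implements the Spread Quantification Index
(SQI), a spread readout that is invariant to detector gain and to the
instrument's dynamic range, so spread can be compared across voltage sets
and across instruments.

## The statistic

For fluorochrome X spreading into secondary detector B, with reference
fluorochrome Y assigned to B (all statistics from compensated single-stain
bead controls, each containing stained and blank beads):

    NF_Y^B  = P / (YSt_B50 − Un_B50)            photon-equivalents per scale unit
    SQI_X^B = (X_B99 − X_B50) × NF_Y^B

where `X_B50`/`X_B99` are the 50th/99th percentiles of X's stained
population in B, `YSt_B50`/`Un_B50` the stained/blank medians of Y's own
control in B, and P a fixed constant (default 9000). Both the spread and
the normalising separation scale linearly with detector gain, so the gain
cancels. SQI values are binned Green (≤120), Yellow (≤220), Orange (≤300)
and Red (>300), alongside the percent of scale units occupied by the
reference separation, `100·(YSt_B50 − Un_B50)/dynamic_range`.

For comparison the classical ISS is also computed:
`ISS = sqrt(σ₊² − σ₋²) / sqrt(ΔF)`, with σ the robust SDs of X's stained
and blank populations in B and ΔF the stained-minus-blank median
separation in X's primary detector — which is why ISS inherits a
square-root gain dependence that SQI does not.

Populations are gated automatically: a two-component normal-mixture EM fit
on the absolute values of the primary-channel intensities, with each
population gated to the first-to-third-quartile interval of its fitted
component.

## Worked example

The package ships a photon-counting simulator (Poisson photon statistics,
binomial quantum efficiency, gain-proportional amplification) that
generates realistic six-fluorochrome single-stain panels:

```python
import sqiflow
from sqiflow.cli_report import controls_from_simulation

out = sqiflow.make_reference_fixtures(seed=1)          # six simulated single-stain controls
controls = controls_from_simulation(out)               # compensate + EM-gate each control
matrix = sqiflow.compute_sqi_matrix(controls)          # SQI for every (fluorochrome, detector)
ssm = sqiflow.compute_ssm(controls)                    # classical ISS for comparison

print(matrix.wide_frame().round(0).to_string())
e = matrix.get("PE-Cy5", "R730")
print(f"PE-Cy5 into R730: SQI = {e.value:.0f} ({e.category}), "
      f"occupancy = {e.percent_occupancy:.1f}%, reference = {e.reference_fluor}")
print(f"PE-Cy5 into R730: ISS = {ssm.get('PE-Cy5', 'R730').value:.2f}")
```

prints

```
              B695   V605   V710  YG610  YG670   R730
source_fluor
APC-R700      17.0   13.0   90.0   10.0   33.0    NaN
BB700          NaN   15.0  111.0   18.0  102.0  193.0
BV605         32.0    NaN  157.0   31.0   26.0   70.0
BV711         54.0   32.0    NaN   11.0   34.0  203.0
PE-CF594      27.0  116.0   60.0    NaN  101.0  111.0
PE-Cy5        46.0   16.0   93.0   42.0    NaN  470.0

PE-Cy5 into R730: SQI = 470 (Red), occupancy = 13.7%, reference = APC-R700
PE-Cy5 into R730: ISS = 2.35
```

PE-Cy5 carries 30% of its photons into R730, whose reference fluorochrome
(APC-R700) is dim, so its spread lands deep in the Red category — a
combination to avoid for any marker that is not on a well-separated
population. Entries near the simulator's autofluorescence floor (no
meaningful spillover) sit at SQI 10–20, Green.

The same workflow runs from the shell on FCS files:

```sh
sqiflow simulate --outdir controls --seed 1        # or use your own single stains
sqiflow compute --manifest controls/manifest.csv --outdir results
```

`compute` writes `sqi_matrix.csv`, `sqi_long.csv` (the machine-readable
source of truth), `ssm_matrix.csv`, `ssm_long.csv`, `gating_report.csv`
and a colour-coded `report.html`. Controls are FCS 3.0/3.1 files listed in
a manifest CSV (`fluorochrome,primary_detector,path,compensated`); raw
files are compensated with the spillover matrix embedded in the file (or
`--spill matrix.csv`), pre-compensated files pass through.

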