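# autorep

Stochastic modelling and single-cell trajectory analysis for a negatively
auto-regulated gene whose operator binding/unbinding speed is tuned by an
inducer.

## The problem

A self-repressing gene — TetR-Venus repressing its own promoter through two
tet operators — is usually expected to produce one tightly controlled
expression level. If an inducer (anhydrotetracycline, aTc) sequesters the free
repressor, it slows the *effective* rates at which the repressor binds
(∝ n², dimer) and unbinds (∝ n, competitor-assisted) its operator, where n is
the free repressor copy number. When operator switching becomes slow compared
with protein turnover (the non-adiabatic regime, ω = f/k₁ ≲ 1), the on and off
gene states imprint separately on the population and **two coexisting cell
fates** appear, switching on the hour scale.

`autorep` provides, for people studying gene-circuit noise and cell-fate
decisions:

* an exact Gillespie simulator and a truncated chemical-master-equation oracle
  for the full reaction network (operator states × free TetR × TetR·aTc
  complexes × internal aTc), with inducer sweeps, Fano factor / CV /
  inhibition-curve statistics and mode detection;
* a two-state Gaussian hidden-Markov analysis of single-cell log-fluorescence
  trajectories: Baum–Welch fitting, Viterbi segmentation, switching
  probabilities, state occupancies and mean residence times with
  censoring-aware brackets;
* a synthetic-data generator (trajectories with ground-truth state paths,
  population snapshots) so the whole pipeline can be exercised and scored
  without external data;
* a CLI: `autorep generate|simulate|analyze|all -c config.yaml -o outdir`.

## Worked example

Generate a synthetic time-lapse data set (163 cells, 40–60 frames at 5-minute
sampling, drawn from the reference two-state HMM) and analyze it:

```bash
cat > config.yaml <<'YAML'
seed: 1
trajectories: {n_trajectories: 163}
analyze: {restarts: 10}
YAML
autorep generate -c config.yaml -o out
autorep analyze  -c config.yaml -o out
python -m json.tool out/report.json
```

The report (abridged; your numbers are identical for the same seed):

```
"emission_means_log10": [2.687, 2.931],
"emission_variances":  [0.0816, 0.0820],
"transition_matrix_low_high": [[0.9786, 0.0214], [0.0410, 0.9590]],
"stationary_weights":  [0.657, 0.343],
"empirical_occupancy": [0.676, 0.324],
"qq_correlation": 0.9997
```

Reading it: the fit recovered the two expression states the generator used —
peak centres near 2.69 and 2.93 log₁₀ fluorescence, per-frame self-transition
probabilities ≈ 0.98 / 0.96 (dwells of hours at 5-minute frames), and roughly
a 2:1 low:high occupancy. `out/residence.tsv` holds the mean residence times
with their censoring brackets, and `out/segments.tsv` the per-cell dwell
segments.

A model-side sweep (this one takes a minute):

```python
from autorep import RateParameters, sweep_inducer
sw = sweep_inducer(RateParameters(), [300, 700, 1100, 1300, 1500],
                   replicates=4, seed=11)
print(sw.summary_frame()[["aTc_ng_per_ml", "fano", "n_modes", "w_low"]])
```

prints a Fano factor rising from ≈3 to ≈60 across the grid and a bimodal
region at 1100–1500 ng/mL whose low-expression weight grows with inducer
(≈0.14 → 0.25 → 0.33) — the signature of the two fates emerging as the
inducer slows operator unbinding. Swap
`RateParameters(unbinding_mode="constant")` to see the control variant whose
high-expression weight grows instead (its bimodal window lies at higher
inducer levels).

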