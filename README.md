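# telosen

Cell-division regimes during replicative senescence in telomerase-negative
budding yeast, analysed from single-cell lineage data.

When telomerase is inactivated, telomeres shorten at each division until
the shortest one signals a DNA-damage checkpoint arrest. Single-cell
microfluidics experiments show that long before the terminal senescence
arrest, lineages experience *non-terminal* arrests — abnormally long cell
cycles followed by a return to normal divisions. This package provides the
statistical and mechanistic machinery to characterise both regimes from
lineage tables of consecutive cell-cycle durations:

* **Arrest classification** — cycles longer than a threshold *D*
  (mean + 3 SD of telomerase-positive cycle durations, ≈180 min) are
  arrests; the last run of long cycles ending in death is the terminal
  (senescence) run, all others are non-terminal.
* **First-arrest hazard model** — the generation *X* of the first
  non-terminal arrest follows the chain
  P(X = k) = p(k) ∏_{j<k} (1 − p(j)), with either a constant hazard
  p(j) = p (X geometric) or a logistic hazard
  p(j) = 1 / (1 + exp(−(j − a)/b)).
* **Telomere-shortening simulator** — 32 telomeres per cell, each losing
  twice the shortening rate with probability 1/2 per division (asymmetric
  end-replication), with two signalling rules: deterministic
  (L₁ + αL₂ ≤ L_min) and probabilistic (p(L) = b·e^{−aL}, forced trigger
  at L = 0).
* **Threshold fitting** — minimises the rank-ordered squared error
  e(θ) = Σ_j Σ_i (G(i,j;θ) − Ḡ(i))² between N ordered simulated
  first-arrest sets and the ordered data, by differential evolution with
  common random numbers.
* **Arrest-run statistics** — gaps between the first two non-terminal
  arrests, geometric laws for run lengths (repair probability q per
  generation), and last-vs-preceding duration comparisons.
* **Synthetic data generator** — produces full lineage datasets with the
  above structure, so the whole pipeline runs and is tested without the
  original dataset.

## Worked example

Running the numbered analysis scripts in order regenerates the whole
analysis on a synthetic dataset (tables land in `results/`):

```bash
python analysis/01_simulate_dataset.py
python analysis/02_classify_arrests.py
python analysis/03_first_arrest_model.py
python analysis/04_fit_telomere_threshold.py
python analysis/05_arrest_run_statistics.py
```

On the default configuration (seed 20210) this prints, among others:

```
threshold D = mean + 3 SD of telomerase-positive cycles = 183.7 min
constant hazard: p = 0.0474, GOF p-value = 2.12e-04 -> rejected
logistic hazard: midpoint = 90.6, scale = 24.0, GOF p-value = 0.466 -> not rejected
deterministic threshold fit: alpha = 2.06e-06, l_min = 82.2
  fraction of ranks inside the 95% envelope: 0.68
probabilistic threshold fit: decay_a = 0.019, amplitude_b = 0.281
  fraction of ranks inside the 95% envelope: 1.00
nonterminal runs (n = 399): q_hat = 0.63, geometric law not rejected (p = 5.35e-01)
terminal runs (n = 173): q_hat = 0.20, geometric law rejected (p = 8.86e-22)
  last vs preceding medians: 710 vs 220 min (Mann-Whitney p = 1.84e-93)
```

Reading: a constant per-generation arrest probability cannot explain when
the first non-terminal arrest appears (the hazard grows with generations),
while the logistic hazard can. Mechanistically, a deterministic
shortest-telomere length threshold is too narrow to capture the spread of
first-arrest timings (only 68% of ranks inside its 95% simulation
envelope), whereas the probabilistic threshold p(L) = b·e^{−aL} captures
it fully — and the best-fitting weight of the second-shortest telomere is
α ≈ 0: only the shortest telomere matters. Finally, the number of
consecutive non-terminal arrests is geometric (constant repair probability
q̂ ≈ 0.63 per generation), but terminal senescence runs are not, and end
in a far longer final cycle — two kinetically distinct regimes.

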