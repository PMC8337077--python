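# Methods

## Model overview

`mitogerm` models the female germline from zygote to the next generation of
mature oocytes as a fixed schedule of division phases acting on mtDNA copy
counts. Mutations are binary (wildtype / deleterious mutant): the state of a
cell is a mutant count `m` out of `M` total copies, not a sequence. Back
mutation, oxidative damage, mutation during the quiescent period, and
nucleoid packaging (multiple genomes per organelle) are all excluded; the
only mutational process is replication error, applied as a Bernoulli event
per newly synthesized wildtype copy with genome-wide probability
`U = g·μ`. The product form is the first-order expansion of
`1 − (1−μ)^g`; at the rates considered (μ ≤ 1e-7, g = 16,569) the difference
is below 1e-6 and the linear form is used throughout.

Two tiers share the schedule. The stochastic tier draws every segregation
(`Binomial(·, 1/2)` per copy), replication (`Δm ~ Binomial(n_wt, U)`), and
sampling event per cell. The deterministic tier assumes an infinite
population with non-overlapping generations and no copy-number fluctuation:
every cell holds exactly `M(t)` copies, with `M` halving during cleavage,
constant during proliferation, and doubling during maturation, and the
population state is a probability vector over `m = 0..M`.

## Parameters

| symbol | meaning | default | units |
|---|---|---|---|
| `M0` | mtDNA copies in zygote / mature oocyte | 2^19 = 524,288 | copies |
| `g` | mitochondrial genome size | 16,569 | bp |
| `μ` | mutation probability per bp per replication | 1e-8 (range 1e-9..1e-7) | — |
| `m0` | inherited mutation load | scenario-specific | fraction |
| `n_cleavage` | cleavage divisions | 12 | — |
| `n_pgc` | primordial germ cells | 32 | cells |
| `b` | extra bottleneck divisions | 0 | — |
| `n_prolif` | proliferation divisions | 18 | — |
| `Nmax` | oogonia (fixed) | 8,388,608 | cells |
| `ξ` | cell-selection epistasis exponent | 5 (1 = linear) | — |
| `p_wt`, `p_mut` | per-copy transfer weights | 0.67 / 0.33 or 0.75 / 0.25 | — |
| `f` | transferred fraction per cyst cell | 0.5 | — |
| `η` | KL stopping threshold | 1e-9 | nats |

The clinical reference is 1/200 carriers (load in [2%, 60%)) and 1/5000
affected (load ≥ 60%), encoded as binomial counts X1/N1 = 50/10,000 and
X2/N2 = 2/10,000. The N_i are not identifiable from published prevalences;
they set the sharpness of the likelihood, not the location of its optimum,
and are overridable.

## Bottleneck bookkeeping

Bottleneck divisions retain both daughters: the germline cell count grows
`2^b`-fold while its total copy pool is conserved, and the subsequent
proliferation phase is correspondingly shorter so the oogonia count stays at
the fixed `Nmax`. The alternative reading — tracking a single daughter per
division, so the germline shrinks to 32 cells of `B̄` copies — destroys
inherited mutations by discreteness whenever `m0 · n_pgc · B̄ < 1` and is
inconsistent with a fixed `Nmax`; we verified that it flips the sign of the
median one-generation load change at low inherited loads. Copy number is
then held at the bottleneck level through proliferation (replicate to
exactly 2× then segregate, no active copy-number control), the
extreme-bottleneck assumption that maximizes segregational variance.

Cells that stochastically lose all copies under tight bottlenecks are
treated as inviable: they carry no load, never survive a cull, and
contribute nothing to cyst pools.

## Selection regimes

- **Individual**: soft selection on prospective zygotes with weights
  `1 − x^5` (resampling in the stochastic tier; multiplicative reweighting
  in the deterministic tier). The concave exponent encodes the clinical
  observation that phenotypes manifest above ~60% heteroplasmy.
- **Cell** (follicular atresia): the 8:1 oogonial cull samples survivors
  without replacement with weights `1 − x^ξ`. Sequential weighted sampling
  is implemented with exponential sort keys (`E_i / w_i`), which is
  distributionally identical to draw-by-draw renormalization; a test checks
  this against exhaustive enumeration. In the deterministic tier the cull is
  the corresponding multiplicative update, applied after the last
  proliferative division and before maturation.
- **Organelle** (cytoplasmic transfer): germline cysts are clones of 8 cells
  descended from one oogonium three divisions earlier. In the stochastic
  tier, every cyst cell donates `round(f·M)` copies (round-half-to-even),
  drawn sequentially without replacement with weights `p_wt`/`p_mut` — the
  Wallenius noncentral hypergeometric process — into the Balbiani body of
  one cell per cyst; nurse cells die. In the deterministic tier the cyst's
  pooled content is the ancestor's content passed through `log2(8) = 3`
  replication operators (so within-cyst loads stay fully correlated), and
  the Balbiani body receives a weighted draw of a fraction `f` of that pool.
  Preserving the clonal correlation matters: treating the 8 cells as
  independent draws from the population distribution averages away the
  high-load tail and drives the equilibrium disease fraction to ~1e-80,
  inverting the comparison between models; with the clonal scheme the
  transfer model sustains a disease fraction of order 2e-4 at wide
  bottlenecks, the order observed clinically.

The transfer kernel defaults to the conditional-weight (Fisher noncentral
hypergeometric) form
`C_mn ∝ C(m,n) p_mut^n · C(M−m, fM−n) p_wt^{fM−n}`; a Wallenius mode
(sequential renormalized draws, computed by direct dynamic programming) is
provided and is the mode matched against the stochastic sampler in
cross-tier tests. The two laws coincide at neutral weights and differ
otherwise; both are validated against independent reference distributions.

## Deterministic tier numerics

Transition kernels are built once per scenario as banded sparse matrices:
hypergeometric segregation (`Hypergeom(M, m, M/2)` per source state),
binomial replication–mutation (`m → 2m + Binomial(M−m, U)`), and their
composition for one proliferative division. Bands extend 9 standard
deviations plus a fixed pad around each source state's mean; entries below
1e-16 of the source state's largest entry are dropped and each column is
renormalized. For `M ≤ 512` exact full kernels are built instead, and tests
require banded/exact agreement to 1e-8. Probability vectors are renormalized
after every operator application (preserved to 1e-10 per step).

The 12 (+b) cleavage divisions are collapsed into a single
`Hypergeom(M0, m, B)` kernel: uniform sub-sampling is consistent under
composition, so the collapse is exact (tested against repeated halving).
The zygote copy number is tied to the bottleneck, `M0 = 2^n_cleavage · B`,
so every stage size is an integer.

Equilibrium iteration applies the full generation map to the zygote-stage
vector until the KL divergence between successive generations falls below
`η = 1e-9` (0·log 0 := 0; states below the truncation floor in the previous
iterate are clipped at 1e-30). For models with individual or cell selection
the stationary state is a genuine fixed point reached from any initial
condition. For the transfer model the fully-mutant state is absorbing (no
back mutation and no fitness penalty), so the reported state is the
long-lived quasi-stationary distribution at which the KL rule triggers; at
small bottlenecks (B ≲ 64 with intermediate weights) the meltdown reaches
near-fixation before the rule triggers, which is itself the scientifically
meaningful outcome (transfer alone cannot maintain quality at tight
bottlenecks).

Two printed-formula ambiguities are resolved by requiring each operator to
reproduce the unambiguous stochastic process (replicate, mutate, segregate),
which cross-tier tests enforce at small `M` against 1e6 stochastic draws per
kernel. The cleavage variance recursion is implemented with coefficient
`2^-(t+1)` on the mutational term (`Var_t = Var_{t-1}/4 + 2^-(t+1) m0`,
equivalently `Var_t = m0 2^-t (1 − 2^-t)` by binomial thinning); the law of
total variance requires this coefficient and enumeration confirms it.

## Scaling choices (what the desk-scale runs do and do not show)

- The unit-test fixture (`make_fixture("test")`) preserves every structural
  ratio at desk size: `M0 = 2^13`, 6 cleavage divisions (same mean
  bottleneck of 128), 8 PGCs, 8 proliferative divisions, 8-cell cysts, 8:1
  cull. It exercises every code path but compresses the division schedule,
  so its mutational input per generation is below the human value.
- Single-generation Δm experiments instead keep the full human division
  schedule per cell (all 30+ replicating divisions, human `M0` and `B̄`) and
  thin the oogonial pool to 8192 cells by uniform subsampling during
  proliferation. Cells evolve independently, so thinning leaves every
  per-oocyte distribution unchanged; only the pool width (hence the
  smoothness of per-replicate means) shrinks. These runs reproduce the
  signs and ordering of the full-width model.
- Equilibrium scans scale the cleavage depth to 6 divisions
  (`M0 = 64·B`, maturation 6 rounds, 4 after pooling) with the full
  18-division proliferation, keeping state vectors ≤ 8193 entries; a scan
  point then takes 0.1–10 s. This removes about 20% of the per-generation
  mutational input relative to the human schedule; equilibrium loads are
  correspondingly slightly lower, but the dependence of each model's fit on
  (μ, B) — the quantity compared across models — is unchanged in form. The
  full-depth scan is available through the CLI for users with more patience.

## Known limitations

- The deterministic tier's constant-copy-number assumption means the
  bottleneck enters only through `B`; stochastic copy-number variation
  (including inviable zero-copy cells) exists only in the stochastic tier.
- With the two-binomial score and equal survey sizes N1 = N2 = 10,000, the
  individual-selection model at a tight bottleneck (B = 8, μ = 1e-8) fits
  the clinical fractions about as well as, or better than, the transfer
  model's best point: drift at 8 copies generates wide variance and concave
  selection trims it to near-clinical fractions. The transfer model's
  distinguishing feature is robustness: it sustains a nonzero disease
  fraction with a thin carrier fraction across wide bottlenecks, where
  individual- and cell-selection fits collapse by hundreds of log-likelihood
  units. Orderings of grid maxima are sensitive to the (unidentifiable)
  survey sizes and grid placement.
- Within-cyst structure is all-or-nothing across the tiers: the stochastic
  tier samples per cell, the deterministic tier draws from the perfectly
  correlated clone pool; the true per-cell draw with 3-division within-cyst
  segregation lies between, and the difference is second-order in the
  within-cyst variance.
- No spatial structure, apoptosis signaling, fission–fusion dynamics,
  nuclear–mitochondrial interaction, or finite-population drift between
  generations.
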