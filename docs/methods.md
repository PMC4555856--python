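# Methods

## Model

A population of `N` players holds binary states (cooperate / defect). Player
`i`'s perceived payoff balance in favour of cooperating is `H_i = p_i + h_i`,
with `h_i = -(i-2)/(N-2)` the intrinsic predisposition (players are indexed
from most to least inherently cooperative; indices are 1-based in all
documentation and file output, converted at the array boundary) and `p_i`
the punishment pressure defined below. All players are redrawn synchronously
each step with probability `P_i = ½[tanh(β H_i) + 1]` of cooperating, i.e.
heat-bath/Glauber dynamics with inverse-temperature-like rationality `β`.
There is no strategy evolution (imitation, replicator) and no interaction
network: influence flows only through the punishment term.

### Punishment

A pool of `n_p` punishers divides total capacity `π n_p` equally over the
`n_f` players currently at fault:

- at-fault defector: `p = π n_p / n_f`;
- defector not at fault: `p = 0`;
- cooperator who would be at fault were she alone to defect: `p = π ñ_p / ñ_f`
  computed in that one-flip counterfactual (she does not punish herself, so
  the cooperators pool gives `ñ_p = n_c − 1`);
- cooperator who would not be at fault: `p = 0`.

The counterfactual deterrent is taken proportional to `π` — the capacity
multiplies the per-defector share exactly as it does for a defector actually
at fault; a deterrent that ignored the capacity would be dimensionally
inconsistent with the rest of the balance.

Pools: `cooperators` (`n_p = n_c`, default), `all` (`n_p = N`), `fraction`
(`n_p = a·n_c`, real-valued — exactly equivalent to rescaling `π → aπ`).

### Fault rules

`uniform` blames every defector. `single_file` blames defector `i` iff player
`i−1` cooperates; `groups` partitions players into contiguous blocks of size
`ν` and blames a defector in group `m` iff at least a proportion `θ` of group
`m−1` cooperates, where `θ` is compared with `≥` against the *actual* size of
group `m−1` (this matters when `ν` does not divide `N` — only the last group
can be short, but its predecessor threshold uses true sizes throughout).
Group 1 — and player 1 under single-file, which is the `ν = 1` special case —
is unconditionally at fault when defecting; without this bootstrap nothing
could ever start the cascade from universal defection. Fault is always
evaluated on the time-`t` configuration; counterfactuals flip exactly one
player and hold everyone else fixed.

The simulator computes all `N` counterfactuals in O(N) per step by tracking
how a single flip shifts the at-fault count (the flipped player's own fault,
a defecting successor under single-file, the possible disabling of group
`m+1` under groups). The per-player reference implementation (`influence`)
evaluates the definitions directly, and the test suite holds the two routes
equal across rules, pools and random configurations.

## Deterministic limit

`β = ∞` is implemented as the continuity limit of the sigmoid: `P = 1` if
`H > 0`, `½` if `H = 0`, `0` if `H < 0`. From all-defect under single-file
targeting this yields the cascade: player 1 cooperates immediately
(`h_1 > 0`), player 2 is a fair coin exactly once (`H = 0` while unpunished),
and thereafter the fault frontier advances one player per step, so the first
passage to full cooperation is `τ = N−1` (coin lands cooperate) or `τ = N`,
each with probability ½, and the speed is `v = N/τ ≈ 1`.

Two bounds govern the cascade. Frontier *advance* at player `i` needs
`π(i−1) > (i−2)/(N−2)`, guaranteed for any `π > 1/(N−2)`. Cooperator
*retention* behind the frontier is stricter: the binding case is player
`j = i−2`, whose counterfactual shares punishment with the frontier player
(`ñ_f = 2`), requiring `π(i−2)/2 > (i−4)/(N−2)`; over the whole run this
needs roughly `π ≳ 2(N−4)/(N−2)²`. Between the two bounds the cascade stalls
(verified numerically: `N = 10` stalls at `π = 0.126` but runs at `π = 0.2`).
Cascade tests therefore run at `π = 0.5`, comfortably above both bounds at
the tested sizes.

## Mean-field analysis

For the uniform rule with the cooperators pool, `n_p = n_c` and
`n_f = N − n_c`, so the expected next-step density closes in `ρ`:

```
G(ρ) = (1/N) Σ_i ½[tanh(β(πρ/(1−ρ) − (i−2)/(N−2))) + 1].
```

Fixed points solve `G(ρ*) = ρ*`; stability uses the map criterion
`|G'(ρ*)| < 1` with a central difference (step `1e−6`), and flow arrows use
`sign(G(ρ) − ρ)`. The two can disagree only for `|G'| > 1` oscillatory cases,
which are reported as unstable; both are exposed. Numerical choices: the
`πρ/(1−ρ)` singularity is guarded at `ε = 1e−9`; root scanning uses a
2001-point grid with Brent refinement to `1e−10`; near-coincident roots from
adjacent brackets are deduplicated at `10×` tolerance. `ρ = 1` is an
attracting boundary limit point whenever `π > 0` and `β > 0` and is reported
with a `boundary` flag rather than as a numeric root; `ρ = 0` is *not* a
fixed point at finite `β` (`G(0) > 0` strictly) and is characterised through
the flow direction instead. A closed-form continuum version (predispositions
uniform on `[−1, 1/(N−2)]`, sigmoid integrated analytically via `log cosh`)
serves as an independent check; discrete and continuum agree to `O(1/N)`.
The mean-field map applies only to the uniform strategy — targeted rules make
`n_f` depend on the detailed configuration — and those are analysed by
simulation only.

## Exact oracle

For `N ≤ 12` the synchronous chain is built densely over all `2^N`
configurations (`T[s→s'] = Π_i [P_i(s) or 1−P_i(s)]`); the stationary law is
obtained by power iteration (tolerance `1e−12`, cap `10^6`), which is
guaranteed to converge since finite `β` makes every entry positive. The
deterministic limit is excluded (the chain may be reducible); deterministic
claims are checked by direct cascade simulation. The oracle validates the
simulator: decoupled (`π = 0`) closed forms are reproduced to `1e−10`, and
Monte-Carlo stationary densities agree within `3·SE` across rules and pools.

## Stationarity, first passage, seeding

Stationarity is operationalised as a fixed burn-in followed by an averaging
window (defaults `burn_in = 500`, `window = 500`, cap `t_max = 2000`), not
adaptive detection, to keep runs bit-reproducible; the estimator simulates
only `burn_in + window` steps. "Full cooperation" for the first-passage time
`τ` means `n_c = N` exactly (first `t ≥ 1`; `τ = 0` for an already-cooperative
start, censored at `t_max` otherwise), with a configurable density-threshold
variant for noisy regimes where unanimity is repeatedly broken by
single-player fluctuations. Speeds `v = N/τ` average over uncensored runs;
an all-censored cell reports `v = 0` with its censored fraction. One master
seed drives everything: realizations use `SeedSequence` spawns, sweep cells
use `SeedSequence((master, i, j))`, so every estimate is reproducible from
`(config, seed)` alone. A sequential asynchronous mode (one random player per
tick) is provided for comparison but synchronous updating is the default —
the mean-field map is defined as a one-step expectation over the whole
population, which is what the synchronous chain realises.

## Perturbations (what the robustness knobs emulate)

`scale_heterogeneity` rescales the spread of `h` about its (exactly
preserved) mean — `λ = 0` is a homogeneous population with the same mean
predisposition. `apply_gaussian_noise` models mis-estimated predispositions;
the noisy profile is *not* re-sorted, so strategies keep acting on the
published ordering. `swap_positions` transposes `round(fraction·N)` distinct
randomly chosen players with uniformly chosen counterparts (sequential
transpositions, self-swap a no-op; the simplest reading of "switching with
random counterparts" — the fraction is exposed so alternatives can be
emulated); values are permuted, never altered. The noise standard deviation
has no canonical value and is a free parameter.

## Scope of the synthetic setting, and limitations

All data is generated by the model itself; the default population (`N = 200`,
linear profile) is a stylised stand-in for a heterogeneous community of
nation-scale actors. Passing tests show internal consistency (simulator ↔
exact chain ↔ mean field ↔ closed forms) and the qualitative phase structure
— bistability under uniform punishment, the trap-free corridor at higher
`π`, cascade recruitment under targeted rules, the strategy ordering
uniform ≤ single-file ≤ groups in achievable area. They do not show that any
real community follows a linear predisposition profile, synchronous logit
choice, or perfectly observed states. Phase-diagram axis ranges
(`β ∈ [0, 5]`, `π ∈ [0, 1.5]` by default; tests use a 10×10 grid at `N = 50`
with 10 realizations per cell) bracket all the qualitative transitions but
are a choice, so area fractions are comparative statements between
strategies on a common grid, not absolute constants. Exact solving is dense
and limited to `N ≤ 12`; there is no mean-field treatment of the targeted
strategies and no continuation-based bifurcation tracking.
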