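# replinet

Analysis of **replicated animal contact-network experiments** from
proximity-logger data: bout assembly, weighted network metrics, balanced
variance-components modelling of group-level treatments, and
SED/LSD-based prediction of how replication choices affect the power to
detect treatment effects.

## The problem

Animal social-network studies usually observe a single group, yet group
composition strongly shapes network structure, so an effect seen in one
network may not generalise. When a treatment (here: introducing an
unfamiliar animal into a settled group of cattle) is applied to whole
groups, the group — not the animal — is the unit of replication, and
honest hypothesis tests must separate *between-group* variation in the
change of behaviour from *within-group* variation. This package implements
that analysis end to end for studies of the standard layout: `n_g`
replicated groups of `n_n` resident animals observed over `n_p`
experimental phases, with contacts recorded by paired proximity loggers.

## What it does

**Preprocessing** (`replinet.contact_log`). Raw directional logger records
are trimmed to the experiment window, detections of ≤ 1 s are discarded as
spurious, the two loggers of each dyad are unioned (a contact starts when
*either* collar sees it and ends when *either* last holds it), intervals
separated by less than the 30-s separation time are merged into contact
bouts, and bouts are assigned to phases (split at phase boundaries so
per-phase durations are conserved).

**Network metrics** (`replinet.network_metrics`). Per (group, phase), a
weighted undirected network with bout-count and total-duration edge
weights; per resident animal, four responses: contacts/day, mean seconds
per contact, contact seconds/day, and weighted degree (contacts per
phase). GraphML/CSV export and exact round-trip import.

**Mixed model** (`replinet.variance_model`). On the log10 scale,

```
y_gap = mu + pi_p + G_g + (G*pi)_gp + A_a(g) + e_gap
```

with fixed phase effects and random group, group-by-phase,
animal-within-group and residual terms. For the balanced design the
variance components are estimated in closed form by equating mean squares
to their expectations (identical to REML at interior solutions); the
phase effect is tested with `F = MS_phase / MS_GxP` on
`(n_p-1, (n_g-1)(n_p-1))` df (Wald `W = (n_p-1) F`), and pairwise phase
contrasts use the standard error of a difference

```
SED = sqrt( 2 s2_GxP / n_g  +  2 s2_e / (n_g n_n) )
```

**Design prediction** (`replinet.design_power`). `SED` and the least
significant difference `LSD(5%) = t_{0.975,v} * SED` (with
`v = (n_g-1)(n_p-1)`) tabulated over candidate designs: varying the number
of networks, the animals per network, or both at a fixed animal total —
with the percentage split of `SED²` into its between-group and
within-group terms.

**Synthetic data** (`replinet.synthetic`). A metric-level simulator
drawing directly from the mixed model (for parameter-recovery and
calibration checks) and an event-level simulator producing raw two-logger
streams with jitter, missed detections and spurious sub-second contacts,
plus ground-truth bouts — so the whole pipeline is testable without any
animal data.

## Worked example

Predict how shrinking a six-network cattle study would affect its power,
using the study's estimated variance components for contact frequency
(group-by-phase 0.0047, residual 0.0129 on the log10 scale) and its
observed maximum phase-mean difference:

```python
from replinet import design_power as dp
from replinet import published as pub

s2_gp, s2_e = pub.VARIANCE_COMPONENTS["freq_per_day"]
c = dp.contribution(s2_gp, s2_e, 6, 5)
print(f"contribution: group-by-phase {c.pct_gp:.0f}%, residual {c.pct_e:.0f}%")

scen = [s for s in dp.scenario_families() if s.label == "vary_replicates"]
table = dp.scenario_table(
    (s2_gp, s2_e), scen,
    max_mean_difference=pub.observed_max_mean_difference("freq_per_day"))
print(dp.render_markdown(table, behaviour="mean frequency of contacts per cow per day"))
```

prints

```
contribution: group-by-phase 65%, residual 35%
**Behaviour: mean frequency of contacts per cow per day**

| No of networks | No individuals per network | SED | Residual df | t stat (5%) | Predicted LSD | Observed max mean difference > predicted LSD |
|---|---|---|---|---|---|---|
| 7 | 5 | 0.05 | 12 | 2.18 | 0.10 | Y |
| 6 | 5 | 0.05 | 10 | 2.23 | 0.11 | Y |
| 5 | 5 | 0.05 | 8 | 2.31 | 0.12 | Y |
| 4 | 5 | 0.06 | 6 | 2.45 | 0.15 | Y |
| 3 | 5 | 0.07 | 4 | 2.78 | 0.19 | Y |
```

Reading the table: 65% of the variance of a phase-mean difference comes
from between-group variation in the behavioural change, so removing
networks inflates the LSD (the smallest detectable difference) much faster
than removing animals would — at three networks the LSD has nearly doubled
relative to seven.

The same analysis runs from raw logger CSVs via the CLI:

```
replinet simulate --level full-study --seed 1 --out sim/
replinet run --contacts sim/contacts.csv --roster sim/roster.csv \
             --config sim/config.yaml --out results/
```

which writes `bouts.csv`, `metrics.csv`, one GraphML per (group, phase),
`model.json`/`model.txt` (components, Wald/F tests, back-transformed phase
means) and `power_<metric>.csv`/`.md` tables like the one above.

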