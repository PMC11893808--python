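# cryodom

Molecular-level organic-matter dynamics in glacier algal habitats, from
ultrahigh-resolution mass spectra to process pools.

Pigmented algal blooms on ice sheets darken the surface and accelerate
melt. How their dissolved and particulate organic matter (DOM / POM)
changes under sunlight and microbial activity is measured by FTICR-MS:
thousands of exact-mass peaks per sample, each resolvable to a unique
CHNOSP molecular formula. `cryodom` is the analysis chain for such
light/dark incubation experiments, for researchers who have per-sample
peak lists (m/z, intensity) from two contrasting habitats — glacier
ice-algae (GIA) and red snow-algae (RSA) — across DOM and two particulate
extracts over a multi-week time series with duplicate measurements and
procedural blanks.

The pipeline:

1. **Formula engine** — noise filtering against a method detection limit,
   optional mass recalibration, CHNOSP formula assignment (±0.5 ppm)
   validated by a homologous-series network (CH₂, CO₂, H₂, H₂O, O blocks)
   with cross-sample consensus, ¹³C₁ isotopologue verification, removal of
   every formula seen in blanks, and duplicate merging (present only if in
   both replicates; mean normalized intensity) into a formula × sample
   matrix whose columns sum to one.
2. **Descriptors** — H/C, O/C, DBE, DBE−O, the modified aromaticity index
   AImod = (1 + C − 0.5·O − S − 0.5·(H+N+P)) / (C − 0.5·O − S − N − P)
   (clamped into [0,1]) and the nominal oxidation state of carbon
   NOSC = 4 − (4C + H − 3N − 2O − 2S)/C; exclusive elemental classes
   (CHO/CHON/CHOS/CHOP), van Krevelen categories (saturated → condensed
   aromatic), and CRAM / oxy-aromatic phytochemical flags.
3. **Dynamics** — each formula's relative-intensity time course is
   classified into the experiment's process pools: *transferred*
   (POM-T0 → DOM, exclusively under light), *photoproduced* /
   *photodegraded* (light-exclusive trends), *heterotrophically produced*
   / *degraded* (dark trends), *refractory* (always present, never
   degraded), with percentages against the design's denominators
   (POM-T0 for transfer, DOM-T0 for production/degradation).
4. **Ordination** — Bray–Curtis dissimilarity, seeded non-metric MDS
   (Kruskal stress-1), and habitat-characteristic formula sets from NMDS1
   loadings beyond ±0.45.
5. **Synthetic experiments** — a generator that emulates the full design
   with planted trajectory classes, realistic noise, blanks, isotopologue
   satellites and replicate dropout, so the entire chain is testable
   against ground truth without any field data.

## Worked example

Simulate a 300-formula experiment and run the full analysis:

```bash
cryodom run -c examples/config.yaml --simulate -o demo_out
```

prints (log lines abridged):

```
INFO cryodom: engine: 300 formulae x 78 merged samples (blank-removed 30, duplicate-dropped 9)
INFO cryodom: labels: {'hetero_degraded': 107, 'unclassified': 94, 'transferred': 71,
                       'refractory': 67, 'photoproduced': 45, 'hetero_produced': 45,
                       'photo_degraded': 22}
INFO cryodom: pipeline complete: 300 formulae, stress 0.0001 -> demo_out
formulae: 300  samples: 78  labels: {...}
```

All 30 formulae planted as blank contaminants were removed
(`blank-removed 30`), nine single-replicate detections were dropped by the
duplicate rule, and the label counts are per (formula, habitat) pairs. The
pool report (`demo_out/pool_report.json`) gives the percentages against
the design's denominators, e.g. for the ice-algae habitat:

```
GIA: 226 formulae, POM-T0 114, DOM-T0 143
     transferred 31.6% of POM-T0
     photoproduced 15.4% / photodegraded 7.7% of DOM-T0
     hetero-produced 16.1% / hetero-degraded 37.8% of DOM-T0
     refractory 33 formulae (14.6% of the habitat)
```

— i.e. roughly a third of the initial particulate formulae were released
into the dissolved pool under light, and over a third of the initial
dissolved formulae were consumed in the dark incubations. The NMDS
(stress ≈ 0.0001: the two habitats are compositionally far apart relative
to within-habitat variation) yields 115 GIA- and 111 RSA-characteristic
formulae at the 0.45 loading threshold, written with their descriptors for
van Krevelen plotting (`demo_out/van_krevelen.tsv`).

Other subcommands operate on existing data: `cryodom assign` (peak lists →
matrix), `describe`, `dynamics`, `ordinate`, and `simulate` alone. Every
artifact is delimited text or JSON and declares the hash of the
configuration that produced it; runs with fixed seeds are byte-reproducible.

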