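# pvsignal

Safety-signal detection for spontaneous adverse-event reports in the FAERS
quarterly-extract dialect: record cleaning, 2×2 disproportionality analysis
with four standard algorithms, Weibull time-to-onset modelling, and
descriptive reporting — plus a synthetic report generator with ground truth
so the whole pipeline is testable without downloading a multi-gigabyte
database extract.

It is written for pharmacovigilance analysts and methods researchers who
want an auditable, scriptable version of the analysis that drug-safety
papers perform on FAERS-style data for a single suspect drug (the shipped
defaults target the IL-23 inhibitor tildrakizumab, but every input — synonym
list, exclusion lists, PT→SOC map, thresholds — is a plain configurable
table).

## The statistics

For a drug–event pair, reports are cross-classified into a 2×2 table
(a = target reports with the event, b = without; c, d likewise for all other
reports; n = a+b+c+d, E = (a+b)(a+c)/n):

| Algorithm | Statistic | Signal criterion |
|---|---|---|
| ROR | ad/bc, CI exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)) | N ≥ 3 and CI low > 1 |
| PRR | [a/(a+b)]/[c/(c+d)], Pearson χ² | PRR ≥ 2, χ² ≥ 4, N ≥ 3 |
| BCPNN | IC = log₂(a/E), Norén IC025 | IC025 > 0 |
| MGPS | EBGM = a/E (simple) or DuMouchel posterior geometric mean | EB05 > 2 |

A term is **positive** when the ROR criterion holds and **significant**
when at least two criteria hold. Time to onset (therapy start → event, in
days) is summarised by median/IQR, binned into 30-day months and 90-day
quarters with growth rates, and fitted with a Weibull law: shape β < 1 means
early-type onset (decreasing hazard), and the scale η is the time by which
63.2% of events have occurred.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (outputs under `results/`, raw generated tables under `scratch/`):

```bash
python analysis/01_simulate.py   # 50,000 reports, 8 quarters, known truth
python analysis/02_clean.py     # dedup -> primary-suspect filter -> exclusions
python analysis/03_signals.py   # 2x2 tables + four algorithms, PT and SOC
python analysis/04_onset.py     # time-to-onset: bins, Weibull, KS, Kruskal-Wallis
python analysis/05_report.py    # demographics + sex-stratified ROR
```

The generator injects four drug–event associations (relative risks 10, 8,
5, 4) into an otherwise-null background. Signal detection recovers exactly
those four, e.g.:

```
PT: 30 terms scored (case count >= 3; 0 below), 4 significant, 4 meet all four criteria
  Urinary tract infection: N=64 ROR=3.55 (2.73-4.61) PRR=3.39 IC025=1.28 EBGM05=2.59 [bcpnn,mgps,prr,ror]
  Psoriasis: N=59 ROR=7.32 (5.53-9.69) PRR=6.95 IC025=2.2 EBGM05=4.91 [bcpnn,mgps,prr,ror]
  Vulvovaginal candidiasis: N=52 ROR=8.82 (6.52-11.92) PRR=8.42 IC025=2.41 EBGM05=5.68 [bcpnn,mgps,prr,ror]
  Therapy cessation: N=36 ROR=3.76 (2.67-5.31) PRR=3.66 IC025=1.24 EBGM05=2.6 [bcpnn,mgps,prr,ror]
```

(N is the exposed-case count; the bracketed flags list which of the four
criteria the term meets.) The onset stage prints the fitted Weibull law for
the 297 reports with usable dates — truth is shape 0.89, scale 269.56 days:

```
Weibull shape 0.865 (95% CI 0.792-0.945), scale 267.3 d (95% CI 232.8-307.0)
onset type: early; KS p = 0.789 (compatible with the Weibull law)
```

i.e. the shape CI covers the generating value, the onset profile is
early-type (hazard highest shortly after starting therapy), and the KS test
does not reject the fitted law.

The same pipeline runs from a shell against any directory of
`AREA_<quarter>.txt` tables:

```bash
pvsignal simulate --out data/ --seed 1
pvsignal run --data-dir data/ --out results/ --level pt,soc --ebgm-mode simple
```

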