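# dsbquant

Absolute quantification of a site-specific DNA double-strand break (DSB)
inside a CTG trinucleotide-repeat locus, from duplex digital-PCR droplet
data — together with the two classical quantifiers it is benchmarked
against (Southern-blot densitometry and DSB-qPCR standard curves) and a
droplet-partition simulator with known ground truth.

Expanded CTG repeats (the myotonic dystrophy type 1 locus) form secondary
structures and break; measuring what fraction of molecules carries a break
at the repeat tract is the readout for nuclease-induction and repair
experiments in budding yeast. `dsbquant` is for the bench scientist or
analyst who has the instrument's per-droplet fluorescence export (or its
gated droplet tallies), a blot scanner's band-volume table, or a qPCR Ct
table, and wants the broken fraction with honest uncertainty.

## The model

A digital-PCR chip splits one reaction into N ≈ 25,000 droplets. Copies of
a target partition into droplets following a Poisson law with mean λ copies
per droplet, so the fraction of negative droplets is e^(−λ) and, from k
positive droplets out of N,

    λ̂ = −ln(1 − k/N),        C = λ̂ / v   [copies/µL]

with v the effective droplet volume. The duplex assay carries two targets:

* **JEM1**, a single-copy control gene that is never cut — detected by a
  HEX hydrolysis probe (green channel) and, like any amplicon, by the
  intercalating EvaGreen dye (blue channel);
* the **CTG locus**, amplifiable only when unbroken — detected by EvaGreen
  alone.

The blue channel therefore shows a *double* positive population (CTG-only
droplets at lower intensity, JEM1-containing droplets above), and

    C(unbroken CTG) = C(blue total) − C(JEM1)
    % unbroken      = 100 · C(unbroken CTG) / C(JEM1)
    % broken        = 100 − % unbroken.

Every positive JEM1 droplet must also be blue-positive, which gives a
built-in cross-channel consistency check. Wilson binomial intervals on k/N
are propagated through the log map, and a delta-method interval (using the
nested-gate covariance) is attached to the percentage.

The Southern route quantifies four bands per lane (full-length allele,
contracted allele, 5′ and 3′ break fragments), each background-subtracted,
as percentages of the lane total; the qPCR route fits a trendline of mean
Ct against percent DSB on standards mixed from digested and undigested DNA
and inverts it for unknowns.

## Worked example

Gated droplet tallies for one chip, as the reader software reports them:

```
$ cat counts.csv
population_label,n_total,n_positive
blue_total,23527,4516
blue_jem1,23527,2863
green_jem1,23527,2844

$ dsbquant quantify-dpcr counts.csv --out-prefix chip
unbroken CTG 135.2 cp/µL | 65.4% unbroken | 34.6% broken
```

Reading: the blue double population corresponds to 341.8 cp/µL and the
green JEM1 reference to 206.6 cp/µL, so 135.2 cp/µL of unbroken CTG
molecules remain — 65.4% of the 206.6 cp/µL genome equivalents — meaning
34.6% of the CTG molecules in this sample carry a DSB. `chip.json` holds
the full-precision values, the 95% interval on the percentage, and the
cross-channel JEM1 agreement (here 0.7%, well inside the 5% tolerance).

The same from Python:

```python
from dsbquant import DropletCounts, quantify_dsb

res = quantify_dsb(
    DropletCounts(23527, 4516),   # blue double population
    DropletCounts(23527, 2863),   # blue upper population (JEM1)
    DropletCounts(23527, 2844),   # green JEM1 (HEX probe)
)
print(res.as_report())
# {'c_blue_total_cp_per_ul': 341.8, 'c_jem1_cp_per_ul': 206.6,
#  'c_ctg_unbroken_cp_per_ul': 135.2, 'pct_unbroken': 65.4, 'pct_broken': 34.6}
```

Other subcommands: `dsbquant simulate` (synthetic chips with ground
truth), `dsbquant quantify-southern` (lane volume CSV → band percentages
and the 5′/3′ agreement flag), `dsbquant fit-qpcr` and `dsbquant melt`.

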