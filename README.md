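# halfsib

Within-half-sib-family linkage mapping of a major gene, built around the
design that mapped a dominant high-ovulation-rate allele in cattle: one
heterozygous sire, ~131 phenotyped daughters from unrelated dams, and a
low-density (~3K) genome-wide SNP panel. The package phases the sire from
his daughters' genotypes, deduces each daughter's paternally inherited
haplotype along every autosome, scans marker brackets for association with
mean ovulation rate, fine-maps the locus from recombinant daughters, and
provides the allele/haplotype-frequency and LD statistics used to
characterize a marker haplotype that tracks the high allele across breeds.
A fully ground-truthed synthetic family generator makes every stage
testable without any external data.

## Who this is for

Quantitative/livestock geneticists analyzing single-family segregation of
a large-effect locus with chip genotypes, and anyone who wants a tested,
scriptable re-implementation of classical half-sib QTL linkage analysis
(sire phasing, bracket regression, recombinant fine-mapping).

## The model

Only markers where the sire is heterozygous are informative. For daughter
*i* with mean ovulation rate *y\_i* (corpora lutea per cycle, averaged over
~4 cycles), birth-year cohort *t(i)* and paternal-haplotype covariate
*x\_i ∈ {0, 1}* at a bracket of consecutive informative markers:

    y_i = mu + year_{t(i)} + beta * x_i + e_i

fitted by OLS per bracket; daughters recombinant within the bracket (or of
unknown state at an end) are excluded from that bracket's fit. The profile
of −log₁₀ *p* for the *x* coefficient across all brackets and autosomes
localizes the gene; *beta* estimates the carrier/non-carrier contrast.

Upstream of the scan:

* **Sire phasing** — chain-majority linking of adjacent informative
  markers: daughters unambiguous at both markers vote for the "same" vs
  "opposite" phase orientation; weak or tied votes break the chain into
  independently labelled blocks.
* **State calling** — per daughter, a minimum-cost dynamic program over
  H1/H2 states (switch penalty 2, mismatch penalty 3 by default) absorbs
  isolated genotyping errors instead of inventing double crossovers;
  ambiguous runs whose flanks disagree are reported as *unknown*, and
  breakpoint intervals span the flanking markers of known state.
* **Fine-mapping** — each recombinant daughter's carrier status constrains
  the causative position to one side of her breakpoint interval; the
  candidate region is the intersection of all such constraints.
* **Population statistics** — allele frequencies by counting with binomial
  SEs, pooled-sequencing peak-height frequency estimates, a ≤3-locus EM for
  haplotype frequencies from unphased genotypes, marginalization, and
  D / r² linkage disequilibrium.

## Worked example

```python
import numpy as np
import halfsib
from halfsib.finemap import classify_carriers

cfg = halfsib.SimConfig(seed=1)          # the study design: n=131, QTL on BTA10
gt, snp_map, phenos, truth = halfsib.simulate_family(cfg)
gt = halfsib.qc_filter(gt)               # 95% call-rate QC
tracks = halfsib.call_all_states(gt, "SIRE")
scan = halfsib.genome_scan(tracks, phenos, gt.snp_map)
peak = halfsib.scan_peak(scan)
print(f"peak bracket: chr{peak['chrom']} at {peak['mid_bp']/1e6:.1f} Mb, "
      f"p = {peak['p']:.2e}")
calls, high = classify_carriers(tracks, scan, phenos)
```

prints (with this seed):

```
peak bracket: chr10 snp10_17..snp10_19 at 18.8 Mb
beta = 0.976 ova, p = 4.31e-23 (-log10 p = 22.4), n = 126
carriers: n=75, mean OR 2.15 +- 0.54
non-carriers: n=56, mean OR 1.17 +- 0.15
true QTL: chr10:14.2 Mb; truth carriers: 75
```

The scan finds the simulated locus on chromosome 10 with overwhelming
evidence (the bracket holding the QTL is one informative bracket away from
the reported peak); carrier classification at the peak recovers the true
carrier count exactly and the configured group means (2.19 ± 0.57 vs
1.11 ± 0.22) within sampling error.

The same pipeline is available from the shell:

```bash
halfsib simulate --seed 1 --out fam/
halfsib phase --genotypes fam/genotypes.tsv --map fam/map.tsv --sire SIRE --out fam/
halfsib scan --tracks fam/tracks.tsv --phenotypes fam/phenotypes.tsv \
             --map fam/map.tsv --out scan.tsv --plot scan.png
halfsib finemap --tracks fam/tracks.tsv --scan scan.tsv --phenotypes fam/phenotypes.tsv \
                --map fam/map.tsv --region 10:6000000-22000000 --out region.json
halfsib ld --genotypes fam/genotypes.tsv --loci snp10_14,snp10_15,snp10_16 --out ld.tsv
```

Readers for deposited-style data are included: plain TSV/CSV phenotypes
(animal id, mean ovulation rate, birth year), long/wide genotype tables,
and PLINK PED/MAP pairs.

## Layout

```
src/halfsib/io.py         containers + readers/writers + QC
src/halfsib/simulate.py   synthetic half-sib families with ground truth
src/halfsib/haplotypes.py sire phasing, state calling, breakpoints
src/halfsib/scan.py       bracket covariates, OLS, genome scan, plot
src/halfsib/finemap.py    carrier classification, region refinement
src/halfsib/popgen.py     allele/haplotype frequencies, EM, LD
src/halfsib/published.py  published breed-survey reference tables
src/halfsib/cli.py        `halfsib` command-line interface
docs/methods.md           model, assumptions, parameter choices, limits
```
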