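# inteinkit

A design toolkit for **split-intein protein trans-splicing**: choosing where
to split a target protein, designing the two precursor constructs that
deliver its halves, and fitting the quantitative assays used to verify
assembly.

Splitting a large protein between two delivery vectors (e.g. two AAV
genomes) and restoring it by intein-mediated trans-splicing is a standard
way around the ~5 kb AAV packaging limit. Success depends critically on the
split site: DnaE-family split inteins require a cysteine as the first
C-extein residue (position C+1), and the five surrounding extein residues
(N-3..N-1, C+2, C+3) modulate splicing efficiency. `inteinkit` scores every
possible split of a target with a position-specific **extein-impact matrix**
— the site score of the 6-mer window `w` around a split at `k/k+1` is the
additive

```
score(k) = Σ_{p ∈ {N-3,N-2,N-1,C+1,C+2,C+3}} M[p, w_p]
```

— ranks the sites, applies the C+1 constraint at selection time (keeping a
low-scoring constraint-failing site as negative control), and turns a chosen
site into deliverable constructs:

* N-precursor `extein[1..k] ++ N-intein ++ tag` and C-precursor
  `C-intein ++ extein[k+1..N] ++ tag` (6×His tags by default), with
  predicted molecular weights of precursors, spliced product and excised
  intein for Western-blot verification;
* codon back-translation (most-frequent or GC-minimizing codon choice),
  restriction screening, BamHI/HindIII cloning flanks, and overlap-PCR
  fragment tiling with junction-oligo melting temperatures.

The assay side provides a four-parameter logistic dose–response model
`y(x) = d + (a−d)/(1+(x/c)^b)` with inverse prediction, qPCR standard curves
(`E = 10^(−1/slope) − 1`) with the standard run-acceptance criteria, titer
quantification, densitometry normalization and fold-change reporting. Seeded
synthetic-data generators make every component testable offline.

## Worked example

Scan the packaged 238-residue GFP target with a synthetic impact matrix in
which the window `GVQCFS` is planted as dominant, then design precursors for
the top site:

```python
import inteinkit as ik
from inteinkit import datasets
from inteinkit.synth import gen_impact_matrix

gfp = datasets.gfp_fixture()
matrix = gen_impact_matrix(seed=11, effect_sd=4.0, planted_window="GVQCFS")
sites = ik.scan(gfp, matrix)
candidates, control = ik.select_candidates(sites, n=2, c1_residues={"C"})
for s in candidates:
    print(s.rank, s.window, s.label, round(s.score, 2))

npu = next(p for p in datasets.intein_registry() if p.name == "NpuDnaE")
cs = ik.design_split_constructs(gfp, candidates[0].k, npu)
for prod in cs.predicted_products:
    print(prod.name, f"{prod.mw/1000:.1f} kDa")
```

prints

```
1 GVQCFS 69/70 733.54
57 KFICTT 47/48 111.77
n_precursor 20.0 kDa
c_precursor 24.5 kDa
spliced_product 26.9 kDa
excised_intein 16.0 kDa
```

The two best cysteine-C+1 windows are `GVQCFS` at 69/70 (planted rank 1)
and `KFICTT` at 47/48; the spliced product is the intact 26.9 kDa GFP —
read as 27 kDa at gel resolution. Fitting the six-point AAV5 transduction
ladder:

```python
doses, pct_gfp = datasets.aav5_dose_response()
fit = ik.fit_4pl(doses, pct_gfp)
print(round(fit.r2, 3), round(ik.predict_4pl(fit, 3.5e4), 1))
# 0.993 51.2
```

i.e. a dose of 3.5×10⁴ Vg/cell already transduces more than half the cells.

The same workflow is available from the shell:

```bash
inteinkit scan --fasta gfp.fasta --matrix matrix.tsv --c1 C --top 3 --out report.tsv
inteinkit design --fasta gfp.fasta --site 69 --intein NpuDnaE --out orfs.fasta
inteinkit fit-dose --csv dose.csv
inteinkit qpcr --csv qpcr.csv --ct 28 --dilution 100
```

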