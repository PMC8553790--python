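# Methods

## Charge model and isoelectric point

Each protein is treated as an unfolded polyion whose ionizable groups
protonate independently.  The groups are the N-terminus, the
C-terminus, and the side chains of Asp, Glu, Cys, Tyr (acidic) and
His, Lys, Arg (basic).  At pH `x` the expected net charge is

```
Z(x) = Σ_basic  n_g / (1 + 10^(x − pKa_g))  −  Σ_acidic n_g / (1 + 10^(pKa_g − x))
```

Every term of `Z` is strictly decreasing in `x`, `Z(0) > 0` (the
N-terminus is always present) and `Z(14) < 0` (the C-terminus is
always present), so `Z` has exactly one root in [0, 14]: the
isoelectric point.  It is found by bisection; the default tolerance of
1e-3 pH units (bracket width) is far below the ~0.01-unit differences
that matter in bulk statistics, and results are reported at three
decimals.  The test suite checks the bisection against an exhaustive
1e-4-step grid search of `Z` for every registered pKa set.

Assumptions worth stating: free cysteine is ionizable (no disulfide
pairing), there are no post-translational modifications, no
folded-state pKa shifts, and phospho/terminal modifications are out of
scope.  These are the standard assumptions of bulk proteome pI
calculators; computed pI of individual folded proteins can deviate
from 2-DE gel positions, but proteome-level distributions are robust.

Four pKa sets are registered, transcribed from their sources:
`ipc_protein` (default) and `ipc_peptide` from the IPC 1.0 calculator
(Kozlowski 2016, Biol Direct 11:55, Table 1), `emboss` (EMBOSS `iep`
defaults) and `sillero` (Sillero & Ribeiro 1989).  Different sets
shift absolute pI by up to ~0.5 units; all downstream statistics take
the set as a parameter, so comparisons should always be made within
one set.

## Molecular weight and composition

Molecular weight is the sum of average (isotope-abundance-weighted)
residue masses — the Expasy/SwissProt table — plus one water
(18.015 Da), reported in Da and rendered as kDa at three decimals.
Monoisotopic masses are deliberately not offered: this is a bulk
descriptive statistic, not a mass-spectrometry tool.

Composition is the fraction of each of the 20 canonical residues among
the canonical residues of the sequence.  IUPAC ambiguity codes
(X, B, Z, J and the rare U, O) are retained under the default "flag"
policy: they are excluded from the composition denominator, contribute
the mean mass of their plausible substitutes (B = Asn/Asp,
Z = Gln/Glu, J = Ile/Leu, X = mean of all twenty, U → Cys, O → Lys) and
carry no ionizable groups.  The rationale for keeping rather than
dropping flagged records is that proteome totals should cover every
predicted sequence; the "strict" policy (reject any non-canonical
code) is available when provenance demands it.  A terminal `*` is a
stop-codon translation artifact and is stripped; an internal `*`
indicates a broken gene model and is an error.

## Aggregation

Host-group summaries are unweighted means over proteins, so a proteome
with more proteins weighs more; the pooled ("kingdom") mean is
likewise per-protein, not a mean of host means.  The
acidic/neutral/basic partition calls a protein neutral iff
|pI − 7| ≤ 0.005, i.e. iff its pI prints as 7.00 at two decimals — a
deliberately narrow window chosen because proteome pI densities are
locally flat near 7, so any wider window would make the neutral share
an arbitrary function of the window width.  Extreme records (longest,
shortest, max/min pI) resolve ties by input order.

## Correlation and PCA

Host-host correlations are Pearson r between the 20-element mean
composition rows of two host groups; residue-residue correlations are
Pearson r between the across-host abundance vectors of two residues.
95% confidence intervals use the Fisher z-transform (the interval
method is a package choice; it is the textbook default for r).

Principal components are extracted by NIPALS — power iteration on the
column-centered matrix with deflation after each component — with
max_iter 100 and a 1e-8 relative tolerance on the score vector by
default.  The matrix is centered but not scaled: all columns of a
compositional percentage table share one unit, and scaling would
inflate the rare residues (Trp, Cys) relative to the abundant ones.
The sign of each component is fixed by forcing its largest-magnitude
loading positive.  NIPALS on small dense matrices is numerically
identical to an eigendecomposition of the covariance; the tests assert
agreement to 1e-6 in explained variance and loading direction.

## Virtual 2D map and modality

The map is a 2D histogram of (pI, log10 MW) with pI fixed to [2, 14]
(values outside are clamped into edge bins with a warning) and the MW
axis on log10 scale — proteome MW spans roughly 0.5 to 1500 kDa, three
orders of magnitude, so a linear-scale density is meaningless.

The modality classifier formalises the visual unimodal/bimodal/
trimodal reading of such maps.  For each marginal a Gaussian KDE is
evaluated on a 512-point grid spanning the data ± 3 bandwidths, with
bandwidth = `bandwidth_factor` × Silverman's rule of thumb
(`0.9·σ̂·n^(−1/5)` up to the standard constant); a mode is a local
maximum whose topographic prominence (height above the highest saddle
towards taller terrain, with the grid boundary as zero ground) is at
least `prominence_frac` (default 0.05) of the global density maximum.
The headline label follows the pI marginal — multimodality of bulk
proteomes is classically a pI phenomenon — while the MW mode count is
reported alongside, never merged.  Both knobs are exposed because the
visual judgment they replace has no canonical parameters; the defaults
were fixed before use and the recovery tests run at exactly these
defaults.  Classification refuses below 50 profiles: KDE peak counts
on smaller samples are noise.  No formal modality test (dip test,
mixture BIC) is attempted — the classifier is a reproducible decision
rule, not a hypothesis test.

## Synthetic proteomes

The generator emulates exactly the features the pipeline consumes:
protein count, right-skewed length distribution (discretised
log-normal, truncated at 5 residues), residue composition, and 1-/2-/
3-component structure in pI.  Sequences are i.i.d. draws from a
component's residue frequencies — order carries no information for
composition, MW or pI, so positional, phylogenetic and codon-level
structure are deliberately absent.  Passing tests therefore
demonstrate correctness of the pipeline's statistics, not biological
realism of any individual sequence.

Component presets tilt the acid/base balance of an average-proteome
frequency vector: the acidic preset raises Asp/Glu (component mean pI
≈ 4.6), the basic preset raises Lys/Arg (≈ 10.1), and the neutral
preset balances charges while raising Cys (10%) and His (5%), whose
near-neutral pKa values buffer the charge curve and keep the
component's pI spread tight (empirical sd ≈ 0.5 at archetype lengths)
— without that buffering a charge-balanced composition yields a very
broad pI distribution, because the net-charge curve is flat around
pH 7.  The elevated Cys is a synthetic device, not a claim about real
viral proteomes (which are Cys-poor).  Host archetypes combine these
presets with equal weights and log-normal lengths (median 450, log-sd
0.3), placing adjacent modes ≥ 4 empirical sd apart, which the KDE
classifier resolves essentially always at n = 2000.

Seeding: one master seed draws the component assignment; record *i*
then uses a stream keyed by (seed, *i*), so generating more records
never changes earlier ones, and FASTA output is byte-identical for a
fixed spec.

## Pipeline determinism and problem sizes

All pipeline outputs are plain TSV/JSON written with fixed float
formats, so identical inputs and seeds give byte-identical files; the
report directory includes the effective configuration and a SHA-256
manifest.  The test suite and the acceptance script run the modality
recovery at 20 seeds × 2000 proteins per archetype and the pI oracle
comparison at a few hundred random peptides — sizes at which every
statistic involved is stable to well within its asserted tolerance.

## Known limitations

- pI is model-based; absolute values depend on the pKa set chosen.
- Composition percentages are compositional data; Pearson correlation
  on them is the field's convention and is reproduced as such, but it
  inherits the closure effects of compositional data.
- The modality label depends on (bandwidth_factor, prominence_frac);
  modes closer than about one bandwidth merge.  Parameters are echoed
  in every `ModalityResult` for provenance.
- Host labels form a closed vocabulary of nine groups; finer taxonomy
  is out of scope.
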