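# Methods

This note documents the models implemented in `madskit`, their
assumptions, the defaults that matter, and the design choices made where
the design was genuinely open. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Cooperative two-site binding model

A DNA probe carries two identical protein-binding sites (CArG boxes). The
protein binds as a pre-formed dimer; monomer–dimer equilibria upstream of
DNA binding are out of scope. With `[P2]` the free dimer concentration
(approximated by the applied amount, since the probe is present in trace
quantity), equilibrium statistical weights of the three probe states are
`1`, `2[P2]/kd1` (two ways to place one dimer), and `[P2]²/(kd1·kd2)`.
Dividing by the partition function gives the band fractions Y0, Y2, Y4.
Assumptions:

- both sites are equivalent before the first binding event (the factor 2);
- applied protein is a valid proxy for free dimer concentration, so `kd1`
  and `kd2` are **relative** quantities in arbitrary protein units;
- `kcoop = kd1/kd2` is dimensionless and invariant under unit rescaling —
  this is the reported quantity and the package verifies the invariance as
  a property.

### Fitting

`fit_cooperative` minimizes the unweighted sum of squared residuals over
all three fraction curves at every lane. Choices:

- **Parameterization:** `log10(kd1)`, `log10(kd2)` — enforces positivity
  without constrained optimization and makes the scale roughly linear in
  information.
- **Multi-start:** a 3×3 grid of starting values geometric over the
  observed protein range, refined with Levenberg–Marquardt; the best of
  nine local fits is kept. The landscape is mildly multimodal when the
  intermediate band is faint.
- **Censoring:** if the fitted intermediate-band maximum over the observed
  lanes is below a detection threshold δ (default 0.02) or the fitted
  ratio exceeds a ceiling (default 200), the fit is reported `censored`
  with `kcoop` pinned at the ceiling and interpreted as a lower bound.
  This operationalizes the practical determinability limit of gel assays:
  very cooperative binding leaves no visible single-dimer band, so only
  "at least ≈200" can be claimed.
- **Ingest renormalization:** measured lane fractions are renormalized to
  sum to 1 when within ±0.05, else rejected — densitometry totals never
  sum exactly.
- Lanes with an undetectable intermediate band are retained as zeros, not
  excluded.

### Identifiability

At high cooperativity the intermediate band peaks at `≈ 1/√kcoop`
(e.g. 0.1 at kcoop = 100), so with fraction noise of sd 0.05 the ratio is
estimated from a signal only about twice the noise. The estimator is
near-unbiased but widely scattered there; `kd1` itself is well determined.
This is a property of the assay conditions, not of the optimizer, and is
the reason censoring exists.

## Single-site saturation model

`[PD] = Pt·[D]/(kd + [D])` with free probe `[D]` as the independent
variable. A convenience conversion (`bound_from_total_probe`) solves the
quadratic mass balance when only total probe is known. The fit uses the
same log-parameter least-squares machinery; a series that is flat at the
plateau drives `kd` to the zero boundary and is returned with
`converged=False` rather than raising, since the plateau is still
informative.

## Synthetic data

The generators define the study conditions under which the package's
statistical claims are tested.

- **Titrations:** 12 lanes, geometric ladder from 0.05 to 3 protein
  (volume) units — the range over which translation mix is titrated in the
  cooperative-binding assays this emulates — with `kd1 = 1` in those units
  as the canonical simulation value. Noise is additive Gaussian (default
  sd 0.05) on each band fraction, clipped to [0, 1], optionally floored
  (faint bands read as 0), and renormalized per lane: the simplest model
  consistent with three quantified bands that must sum to the lane total.
  The true lane-to-lane noise magnitude of gel densitometry is not
  published; sd 0.05 is a modeling choice. Lanes where flooring removes
  all bands are recorded as all-free probe. With sd 0 and no floor the
  simulated fractions are bitwise equal to the forward model.
- **Saturation series:** probe ladder geometric from 0.05 to 32 DNA
  units, matching the saturation-assay protocol; the additive sd is scaled
  by `Pt` so sd 0.05 perturbs by 5% of the plateau, the magnitude
  analogous to the titration noise.
- **Families:** sequences are drawn column-independently from per-column
  amino-acid distributions. This deliberately ignores phylogenetic
  covariation and insertion/deletion processes; it is adequate for testing
  per-column statistics (similarity, frequencies, hydropathy) and nothing
  more. Passing tests therefore show that the pipeline detects the
  conservation structure it is pointed at, not that real alignments have
  that structure. Presets: `SEP3-like` places P(L) = 0.95 at the 12
  interacting leucine positions and conserved hydrophobics at the three
  extra interface positions; `AP3-like`/`PI-like` replace the central
  interface leucines with the alternative residues those subfamilies
  prefer (notably threonine at 157 and glutamine at 164 for AP3-like);
  `background` is diffuse everywhere. Non-interacting columns cycle
  through five diffuse polar/charged/mixed templates with maximum
  per-residue probability 0.3.

## Conservation scoring

Each unordered residue pair (a, b) in a column scores
`s(a,b) = ½(B(a,b)/max_row(a) + B(a,b)/max_row(b))`, with `max_row`
taken over the 20 canonical residues. "Normalize by the maximum value of
the respective amino acid" is ambiguous for a pair; the symmetric mean of
both single-sided normalizations is used so that `s` is symmetric, with
single-sided variants available via the `normalization` option. Because
BLOSUM row maxima lie on the diagonal, an invariant column scores exactly
1. Negative normalized scores are **kept**: the statistic is an average
and flooring at zero would bias class comparisons. Gaps and `X` are
excluded pairwise, not column-wise, so columns overlapping the PI-lineage
four-residue deletion remain analysable; columns with fewer than two
usable residues are flagged missing. BLOSUM40 (loaded from biotite's
standard matrix set) is the default, matching the ~40% identity regime of
K-domain alignments.

### Site-class statistics

The interacting-site partition defaults to the 12 interface leucines
(101, 108, 115, 120, 123, 128, 131, 135, 154, 157, 164, 171) plus three
further hydrophobic interface positions (105, 112, 150) to complete the
15-residue set; the remainder beyond the 12 leucines is not enumerated in
the published record and is an explicit user-overridable default. Classes
are compared with a two-sided Mann–Whitney U test. The exact branch
enumerates all rank assignments (ties via midranks) and is used when both
classes have ≤ 8 observations — beyond that the enumeration count
explodes combinatorially — otherwise the tie- and continuity-corrected
normal approximation (scipy) is used. Per-subfamily computation is the
default; pooled analyses are possible by relabelling.

### Frequencies and hydropathy

Per-site frequencies are over non-gap residues; residues under the
collapse threshold (default 5%) pool into "others", and rows sum to 1.
Hydropathy defaults to the Kyte–Doolittle scale (Hopp–Woods also
available); scales are named, pluggable tables.

## Heptad and wheel conventions

Register phases are anchored per subdomain, because the published
assignments (145 → 'd' in K2; 161, 168 → 'a' and 164 → 'd' in K3) are
mutually inconsistent under a single phase. Defaults (SEP3 numbering):
K1 94–119 with 'a' at 98 (placing the zipper leucines 101/108/115 at
'd' — a choice, since K1's phase is not pinned by published assignments),
K2 126–149 with 'a' at 142, K3 150–181 with 'a' at 161 (placing the
M150/L157/L164/L171 stripe at 'd'). Spans and anchors are plain data and
can be replaced wholesale. Positions outside annotated spans are errors,
not guesses.

Helical wheels advance 720/7 ≈ 102.86° per residue (7 residues per 2
turns), with register 'a' at 0° by convention; 'a' and 'd' of one heptad
end up ≈51.4° apart, the signature of the hydrophobic seam.

The periodicity score slides a window (14, 21, or 28 residues, the
conventional sizes) and takes the best over the 7 phases of the fraction
of 'a'/'d' positions occupied by hydrophobic residues {L, I, V, M, F, A,
W, Y}; each residue reports the maximum over covering windows. It is a
transparent substitute for dedicated coiled-coil predictors (COILS), not
a probabilistic reimplementation, and is intended for ranking candidate
regions only.

## Constructs and probes

Mutation strings use 1-based full-protein coordinates (`L164P`,
hyphen-joined doubles like `E161L-N168L`); application verifies the
wild-type residue at every site and is exactly invertible. Chimeras
replace a host region by a donor region (both 1-based inclusive); the
donor region homologous to a host span must be supplied by the user, as
cross-protein homology maps are alignment-dependent.

Probe fixtures are stored letter-for-letter as designed (the single-site
probe's printed complementary-strand annotation is normalized to the
standard 5'→3' reading, recorded in its FASTA header). Motif scans are
0-based half-open internally, 1-based inclusive in reports; "distance"
between two boxes is start-to-start, which equals center-to-center for
equal-length motifs. Box spacing in helical turns uses 10.5 bp/turn.

## Problem sizes and determinism

Statistical tests run at the sizes the claims are stated for: 78-sequence
families for the conservation pipeline, 2000 sequences for
law-of-large-numbers convergence checks, 50 seeded replicates for
parameter-recovery medians. All generators are pure functions of
(parameters, seed), and pipeline outputs are plain TSV stamped with the
seed and a configuration hash, so identical runs are byte-identical.

## Known limitations

- The binding model ignores dimerization equilibria, probe depletion, and
  lane-to-lane loading variation beyond the renormalization step.
- Censored fits report a lower bound, not an estimate; comparing censored
  values across constructs is only meaningful as "≥ ceiling".
- The family generator cannot produce covariation, indels, or
  phylogenetic structure; conclusions about real alignments require real
  alignments.
- The periodicity score is not a coiled-coil probability and should not
  be compared across proteins with different composition.
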