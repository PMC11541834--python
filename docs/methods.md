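# Methods

This note records the models implemented in `scaffdeco`, their assumptions,
the parameters that matter, and the design choices made where the design was
genuinely open. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Scope and division of labour

The package implements the *orchestration* layer of a de novo
design-and-triage campaign: fragmentation, a generative decorator model,
library profiling, funnel screening, end-point energy aggregation and
trajectory analytics. Physics engines are deliberately upstream: docking
scores, per-frame MM-PBSA components and MD trajectories enter as tables and
coordinate files. RDKit provides all molecular parsing, canonicalization,
InChI, QED, the 2D descriptor catalogue and Murcko scaffolds; scikit-learn
provides PCA; scipy the rank tests. The recurrent model, its autodiff core,
and all trajectory metrics are implemented here in numpy.

## Fragmentation

A cut is any acyclic single bond between heavy atoms. The ring-containing
side becomes the scaffold; if both sides contain rings, both orientations are
emitted (this is the convention under which pair counts equal the brute-force
bond enumeration used as the test oracle). Multi-cut slicing is out of scope:
the decorator consumes exactly one attachment point per part. Attachment
points are dummy atoms (`[*]`/`*`), which survive canonicalization.

Decoration constraints default to HBD ≤ 5, ClogP ≤ 5, rotatable bonds ≤ 5,
evaluated on the decoration with its attachment dummy replaced by hydrogen.
Definitions are the community defaults: Lipinski donor counting, Crippen
atomic-contribution LogP, and the strict rotatable-bond SMARTS (amide C–N
excluded). Pair libraries deduplicate on the ordered (scaffold, decoration)
canonical-SMILES tuple and split 8:1:1 by a seeded shuffle, remainder to
train.

## Decorator model

Architecture: embedding (default 32) shared between scaffold and decoration
tokens; a bidirectional LSTM encoder (one layer per direction by default)
whose per-position forward and backward hidden states are summed, and whose
summed final states initialize every decoder layer; a two-layer LSTM decoder
with Luong-style global dot-product attention over all encoder positions at
every step; output projection from tanh(W_c·[context; hidden]). Training
minimizes mean per-token cross-entropy of the decoration given the scaffold
with Adam (lr 1e-3, batch 32). Gated (LSTM) cells were chosen because the
bidirectional-generation lineage this design follows uses gated recurrence;
the attention form is the standard "global" variant. The decoration is read
left-to-right by default; a right-to-left direction flag exists because
SMILES can be grown from either end, but the two directions are trained
separately, not jointly.

The desk preset (~118k parameters with a typical vocabulary) is the tested
configuration; a `paper_scale` preset (embedding 64, hidden 256, 2+2 layers)
is provided for larger corpora without any parameter-count guarantee. The
published model this mirrors reports ~1.27M parameters with four hidden
layers; its exact widths are not recoverable, so no attempt is made to match
the count.

Implementation: with no deep-learning framework among the dependencies, the
model runs on a ~250-line reverse-mode autodiff core (`_autograd.py`)
validated against finite differences in the test suite. Everything is
float64 numpy; training is bit-reproducible for a fixed seed, which the
tests assert literally.

Sampling draws tokens from the temperature-scaled softmax until END, masking
PAD/START/UNK so every emitted sequence is decodable; greedy decoding is the
temperature → 0 limit. `generate_library` attaches sampled decorations to
their scaffold, drops unparseable products, deduplicates by InChI, applies
the MW ≤ 500 Da filter (boundary kept) and reports the attrition chain
n_novel ≤ n_unique ≤ n_valid ≤ n_sampled. Novelty is measured against the
attached training pairs.

Training-scale choices: the memorization benchmark uses a 20-pair
distinct-scaffold corpus, 300 epochs, desk preset — small enough to train in
well under a minute on one CPU while exercising encoder, attention and
decoder end to end. Loss below 0.1 nats/token and ≥ 90% greedy reproduction
of the training decorations are the pass conditions the tests check.

## Library profiling

QED is RDKit's desirability-function aggregate; the SA score (fragment
contributions + complexity penalty, 1 easy – 10 hard) is loaded from the
RDKit distribution's contributed implementation together with its published
fragment-frequency table, so no network access is involved. Chiral-center
counts include unassigned potential stereocenters, since unassigned centers
carry the same synthesis burden the statistic is meant to capture. The
chemical-space projection standardizes the full RDKit 2D descriptor
catalogue (~210 descriptors, recorded by name in the result), drops constant
or non-finite columns (also recorded), and takes principal axes from the
pooled set so that identical libraries land on identical point clouds.
Distribution comparisons use the two-sided Mann–Whitney U test (docking-score
distributions are not normal; the published comparison names only a p-value
threshold, not a test). Identical constant samples return p = 1 by
convention. Histogram "peak position" summaries are computed as the argmax of
a Gaussian KDE with Silverman bandwidth and are descriptive only.

## Screening funnel

Retention is ⌈f·N⌉, the rule that reproduces both published retention counts
(30% of 3,890 = 1,167 exactly; 20% of 1,167 = 233.4 → 234). Scores follow
the docking convention (lower = better; a per-stage flag can invert). Ties
break by score then lexicographic id, making results independent of input
order. Scorers are pluggable callables; shipped scorers are `mock` (seeded
hash-based, for pipeline tests) and `column` (scores read from an ingested
CSV, the intended production path for exported docking results). The
published three-stage screen reports 21 XP survivors where the ceiling rule
gives ⌈0.1·234⌉ = 24; the discrepancy (plausibly docking failures) is not
modelled — the per-stage attrition log makes such losses visible instead.

## Binding energetics

The end-point identities are applied to component *means*; SDs are sample
(n−1) standard deviations and are reported, not propagated. The polar and
nonpolar solvation rows are read as com − (pro + lig): the source prints the
ΔE_PB equation without parentheses, and only this reading closes the
reference table (closure within ±0.002 kcal/mol, the printed rounding).
−TΔS is an input per system, since the entropy method behind the reference
values is unstated; an interaction-entropy estimator from ΔE_MM fluctuations
is provided but off by default. Ki uses R = 1.9872041e−3 kcal·mol⁻¹·K⁻¹ at
298.15 K — the temperature that reproduces all mutually consistent printed
Ki values to three significant figures (300 K does not). One reference entry
(M4) is inconsistent with its own ΔG_bind by three orders of magnitude;
`ki_consistent` flags it and the package makes no attempt to reproduce it.
Snapshot selection takes the last `window` ns at a fixed interval (times in
(total−window, total]); the interval must divide the window and yield at
least two frames, matching the ≥ 2-frame requirement of the SD computation.
Per-residue decomposition selects residues with |total| above a threshold
(default 1.0 kcal/mol) and labels each with its largest-magnitude component.

## Trajectory metrics

Coordinates are Å internally; Rg and SASA are reported in nm and nm². RMSD
fitting defaults to backbone atoms; ligand-style series can be computed by
passing an explicit selection after a protein fit. The H-bond criterion is
the common MD default (D–A ≤ 3.5 Å, H–D–A ≤ 30°), as none is stated in the
source. SASA is Shrake–Rupley with a 1.4 Å probe and 960 golden-spiral
points per atom; a boundary tie-break assigns points lying exactly on a
neighbouring sphere to the lower-index atom, so exactly coincident spheres
count once. DCCM masks zero-variance atoms as undefined. The FEL uses
G = −RT ln(N/N_max) on a 50×50 histogram over the observed (RMSD, Rg)
ranges; empty bins are NaN and the most-populated bin is exactly 0.

## Synthetic data: what it emulates and what it does not

The molecule generator is an attachment grammar — a ring core from a fixed
set of 12 common (hetero)aromatic and saturated systems plus up to 4
substituents from a 20-fragment alphabet attached at ring carbons — aiming
at MW 150–550. Molecules are valid and ring-containing by construction,
which is what makes slicing and profiling tests deterministic; the grammar
does not emulate real SAR, stereochemistry-rich scaffolds, or the property
correlations of a curated inhibitor set, so passing tests demonstrate
pipeline correctness, not chemical realism. Scored tables draw three tier
scores and an affinity around a shared latent quality with duplicate redraw,
guaranteeing the injectivity the retention arithmetic assumes.

Synthetic trajectories add isotropic per-atom Gaussian noise (SD σ_r per
residue) to an extended-chain reference, giving closed-form ground truth:
RMSF = σ√3 and DCCM block correlation = ρ for planted correlated blocks
(blocks mix a shared per-frame latent so that paired — and within-block —
atoms correlate at ρ while keeping per-atom variance σ²). There is no
global rigid-body motion: recovery checks therefore run without
superposition, because least-squares fitting absorbs part of a planted
collective mode (and its translation removal subtracts the block mean),
biasing the recovered correlation downward; with fitting enabled the RMSF
estimate still carries only the small 6-DOF bias (≈ 2% at 50 residues),
which is why the recovery tolerance is 5%. Energy-frame generation draws
components independently at the specified means/SDs (defaults: the M1
reference column); real com/pro components are strongly correlated, so the
synthetic ΔG_bind has a larger frame-to-frame SE (~2 kcal/mol at 5,000
frames) than a real run would.

## Numerical and degenerate-input conventions

Sample SDs use n−1 and require ≥ 2 frames. The tokenizer rejects unbalanced
brackets; sequences longer than 120 tokens are dropped from training with a
count. Funnel stages error on unscored or non-finite records, naming the
record. `fel` of a constant series yields a single zero bin; equally
populated maxima are all zero. Immobile atoms give NaN DCCM rows. The Ki
round trip holds to 1e−9 relative tolerance.

## Known limitations

No docking or PB solver; no multi-cut fragmentation or ring-bond (RECAP/
BRICS) rules; no reinforcement-learning fine-tuning; the desk-scale model is
not expected to reproduce the published 3,890-molecule library or its
distribution modes, which depend on an unpublished 625-compound training
set. CPU-only float64 training is slow beyond a few thousand pairs.
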