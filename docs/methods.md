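# Methods

This note documents the models, thresholds and design choices behind
`xlink3d`, in the order the pipeline runs them. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Coordinate model and structure I/O

Structures are parsed with gemmi into a minimal chain → residue → atom model.
Author residue numbering (`seq_id` + insertion code) is the coordinate system
for every site mapping, because residue-resolution crosslink tables reference
author numbering. Only the first model of multi-model files is used
(`model_index` overrides); alternate locations collapse to the
highest-occupancy atom, ties going to altloc `A` and then file order.
Hydrogens are retained but flagged and excluded from all distance work, since
most deposited structures lack them. Modified residues map to standard
parents through a small pinned alias table (PSU→U, MSE→MET, ...); unmapped
names become kind `other`, are excluded from feature tables, and trigger a
logged warning. Chain polymer class is a majority vote over residue kinds,
with O2′ presence separating RNA from DNA when residue names are ambiguous.

## Interface geometry

All thresholds live in `GeometryConfig` and are overridable (also from the
CLI). The defaults were pinned to reproduce textbook interaction geometry and
are deliberately conservative:

| quantity | default | rationale |
| --- | --- | --- |
| contact cutoff | 4.5 Å (inclusive) | minimum heavy-atom distance defining "direct contact" |
| H-bond donor–acceptor | ≤ 3.5 Å | heavy-atom-only calling; no hydrogen positions required |
| stacking interplane angle | ≤ 30° | acute angle, min(θ, 180°−θ) |
| stacking vertical separation | 2.0–4.5 Å | brackets the ~3.4 Å π-stack rise |
| stacking lateral offset | ≤ 3.0 Å | rings must actually overlap |
| pseudo-pair vertical | ≤ 1.5 Å | coplanar (paired), explicitly not stacked |
| pseudo-pair H-bonds | ≥ 2 | multiply hydrogen-bonded, like a base pair |

Planes are least-squares fits (SVD); the normal's sign convention (positive
z, ties broken toward positive x then y) makes outputs reproducible. The
centroid–centroid vector is decomposed along the averaged normal (vertical)
and off it (lateral). Collinear moieties raise a degenerate-plane error and
are skipped with a warning.

Planar moieties catalogued for stacking: the purine/pyrimidine ring systems;
Phe/Tyr six-rings; the Trp nine-atom indole; the His five-ring; the arginine
guanidinium (NE, CZ, NH1, NH2); and peptide-bond planes (CAi, Ci, Oi, Ni+1,
CAi+1) of consecutive residues whose C–N distance confirms the bond. Pseudo
pairing additionally considers the Asn/Gln amide and Asp/Glu carboxyl groups.
The exact atom sets for the guanidinium plane and the lateral-offset
definition are our pinned choices; other annotation tools may differ in edge
cases. Typed interactions (H-bond, stack, pseudo pair) whose residues fail
the generic 4.5 Å test are still retained and those residues count as
contacting — occasionally a typed contact sits slightly above the generic
cutoff.

Sugar pucker uses the five ring torsions ν0…ν4 and the
Altona–Sundaralingam relation; the implementation computes
`P = atan2((ν4+ν1)−(ν3+ν0), 2 ν2 (sin 36° + sin 72°))`, which handles the
ν2 < 0 branch shift automatically, and
`τm = hypot(ν2, ((ν4+ν1)−(ν3+ν0))/(2(sin 36°+sin 72°)))`. The ten classes
are the 36°-wide bins of P centered at 18° + k·36°; family N covers
P ∈ [270°, 360°) ∪ [0°, 90°). Base orientation is anti iff |χ| ≥ 90°, with χ
the O4′–C1′–N9–C4 (purine) or O4′–C1′–N1–C2 (pyrimidine) torsion. The
torsion implementation matches gemmi's sign convention exactly. Missing
atoms mark the feature as absent rather than failing the residue.

RNA pairing context calls base pairs from ≥ 2 base-moiety hydrogen bonds plus
coplanarity (≤ 30°), one partner per nucleotide (greedy, most bonds first,
covalent neighbors excluded). Loop elements come from a nested-pair run
analysis: paired residues are helix-internal when both sequence neighbors
continue the helix, else helix-end; unpaired runs are hairpin loops when
their flanks pair each other, bulges when the partner strand has no gap,
internal loops when it has an unpaired gap, junctions otherwise; runs at
chain termini are terminal-ss, and chains with no pairs at all are
isolated-ss. This is a deliberate subset of full base-pair taxonomy
(Leontis–Westhof classes and suite assignment are out of scope).

## Feature schemas

The per-nucleotide schema (`nt-v1`, 246 columns, 15 groups) is a pinned
reconstruction: eight typed-contact groups × (20 amino acids + 6 categories)
= 208 counts; pucker one-hots (10 + 2); orientation (2); secondary element
(8); pairing status (2); 5′/3′ neighbor-stacking flags (2); per-class totals
(8); and an interface summary (contacting-residue count, H-bond total, typed
interaction total, minimum contact distance — 0 when no contact exists). The
amino-acid categories (positive {R,K,H}, negative {D,E}, aromatic {F,W,Y,H},
aliphatic {A,V,L,I}, hydrophobic {A,V,L,I,M,F,W,C,P}, polar {S,T,N,Q,Y,C,H})
overlap deliberately, so category aggregates are sums of their member
columns — an invariant the tests enforce. Peptide-bond stacks span two
residues; for counting they are attributed once, to the N-terminal residue
of the peptide unit, which keeps class totals equal to the sum of the 20
per-amino-acid columns. The schema version travels in every exported TSV
header and import validates column count and order; alternative schemas can
be registered alongside `nt-v1`/`aa-v1`.

The per-amino-acid schema (`aa-v1`, 36 columns): H-bond counts by base ×
RNA moiety × protein moiety (4×3×2 = 24), stacking and pseudo-pair counts
per base (4 + 4), and a summary block (4). Identity blocks are optional:
base one-hot + overlapping dinucleotides (4 + 16 + 16) for nucleotides;
amino-acid one-hot (20) plus preceding/following dipeptide categoricals,
expanded one-hot only over pairs observed in the table to avoid 400-wide
constant-zero blocks.

## Crosslink labels

Offsets are 0-based and end-exclusive everywhere. The position frequency is
(#instances crosslinked at p) / n with n the number of instances carrying at
least one crosslink; this denominator is pinned (the natural reading of
"instances with crosslink sites ... frequency among all instances"), and the
all-matched-instances variant is available behind a flag. The calling rule —
crosslinked iff (n ≥ 20 and f ≥ 0.3) or (n ≥ 10 and f ≥ 0.5) — is monotone
in counts, a property the suite tests. Window extensions (±1–2 nt) rerun the
counting on extended coordinates; called positions outside the modeled
ligand are reported but cannot be labeled. Protein sites are mapped by
global pairwise alignment (match +1, mismatch −1, gap −2, Biopython
PairwiseAligner) and accepted only when the aligned letter matches and the
±10-column neighborhood identity is ≥ 90%. Redundant structures for one
domain are resolved lexicographically: most crosslink evidence, then most
non-zero features, then smallest accession. Contacting/non-contacting
frequency splits report undefined (NaN), not zero, for empty groups.

## Classification protocol

SMOTE generates synthetic minority rows as `x + u·(x′ − x)` with u ~ U(0,1)
and x′ one of x's k = 5 nearest minority neighbors, up to a 1:1 class ratio;
k shrinks with a warning when the minority is smaller, and a single minority
row is an error. SMOTE runs *inside* each training fold only — applying it
before the split would leak interpolants of held-out points into training
and bias the AUC upward; a flag reproduces the leaky variant for comparison.
Cross-validation is stratified 10-fold (reduced with a warning when the
minority is too small); held-out scores are pooled for a single AUC. The
bootstrap CI protocol is pinned as: resample rows with replacement, retrain
with fixed hyperparameters, score out-of-bag rows, take 2.5/97.5 percentiles
over 2000 refits (tests and the demo pipeline use fewer refits; the
parameter is explicit everywhere). Grouped (leave-complex-out) CV is
available as an option since rows from one complex are correlated; the
default remains row-level stratification.

Mean GiniDecrease is computed by direct traversal of each tree: the sum over
splits of node-size-weighted impurity decrease, normalized by root size and
averaged over trees. This is intentionally *not* sklearn's normalized
`feature_importances_`, so hand-computable cases keep absolute values (a
perfect single split of a balanced node yields exactly 0.5). Ranks use
average tie-breaking, rank 1 = most important.

The robustness score for feature s is
`R_s = −log10((Σ_i I(r_is < r_s) + 1)/(N + 1))` over N label permutations,
each retrained with the same parameters (fresh forest/SMOTE seeds per
permutation). The +1 pseudocounts are the only departure from the plain
fraction, which is undefined at zero exceedances; they cap R_s at
log10(N + 1) (≈ 3.30 at N = 2000). The strict inequality is kept as defined.

Direction signs come from an elastic-net logistic regression on standardized
features; α (mixing) and λ (penalty, mapped to sklearn as C = 1/λ) are
either fixed or selected on a grid by cross-validated AUC. A zero
coefficient reports sign `0` (undetermined) rather than guessing. Whether a
signed importance display should multiply Gini by the sign or merely color
it is presentation-dependent; magnitude and sign are stored separately and
the scatter plot uses the signed product.

Alternative classifiers (logistic regression, RBF-SVM, XGBoost, and a
model-averaged network that fits the same single-hidden-layer MLP under
several seeds and averages predicted scores) run under the identical
SMOTE-inside-fold CV protocol.

## Synthetic data: what it does and does not show

Geometry fixtures are idealized: regular-polygon rings at literature bond
lengths, posed exactly at requested angles/offsets, riboses built by
adjusting an out-of-plane displacement model until the analyzer's recovered
phase matches the target (< 1° closure over a 36-phase sweep), and an
untwisted Watson–Crick ladder hairpin whose pairing table is known by
construction. They verify that the analyzers recover constructed geometry
exactly; they do not probe thermal disorder, non-ideal ring geometry,
alternate conformers or crystallographic artifacts.

Simulated feature tables draw counts class-conditionally: Poisson(λ = 0.5)
everywhere, with informative features' rates multiplied by e^β (β = 1.5,
rate ratio ≈ 4.5) in positive rows, at exactly the study imbalance
(43:171). For Poisson class-conditionals this is *identical* to the logistic
label model Bernoulli(sigmoid(β·x + b)) with
b = log(n_pos/n_neg) − k·λ·(e^β − 1), which supplies the closed-form Bayes
oracle used to sanity-check classifier AUC. Passing tests on these tables
shows the protocol recovers a strong, independent, sparsely-injected signal
at the study's sample size; it does not show that real interface features
are this clean — real features are correlated (category aggregates are sums
of members), the signal is weaker (published-scale AUCs are ~0.7–0.8), and
rows from one complex are not independent.

## Numerical choices and problem sizes

Angles are acute throughout; torsions follow the standard sign convention
(verified against gemmi). Ties: altloc resolution (occupancy, then 'A',
then order), importance ranks (average), redundancy selection (accession
string). Degenerate inputs: collinear planes skipped with warnings, missing
ring/χ atoms mark features absent, empty contact groups report NaN. The
test suite and acceptance script scale stochastic components to single-CPU
sizes as a package choice: permutation robustness at N = 200 over ten
replicates for the recovery analysis (N = 2000 remains the default in
`PermutationConfig`), bootstrap CIs at 25–200 refits in tests and the demo
pipeline, and the full-enumeration Fisher cross-check over all 2×2 tables
with margins ≤ 30. All randomness descends from explicit seeds; the
pipeline derives named substreams from one master seed and its reruns are
byte-identical (SVG output pins the hash salt and omits timestamps).

## Known limitations

* The 246-column schema is a faithful reconstruction pinned to the printed
  group and column totals, not a copy of an external feature list; per-class
  totals and conformation dummies are our allocation of the remainder.
* Stacking/H-bond thresholds approximate, but cannot exactly reproduce,
  the internal rules of the original annotation programs they stand in for.
* The secondary-structure element classifier handles nested pairings;
  pseudoknots fall out as junction/ss labels.
* The binomial rate comparison pins H0 to group b's rate with n = n_a; other
  constructions (pooled rate, two-proportion tests) give different p-values,
  and the construction is recorded in output metadata.
* Real-data integration (downloading deposited structures, CLIP or
  interactome-capture datasets) is intentionally out of scope; file-format
  interfaces are the boundary.
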