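# Methods

`cardiocomm` re-implements, as a tested library, the analysis chain used
in plate-based (SORT-seq / CEL-seq2-style) single-cell studies of the
ischemic mouse heart: collision-corrected UMI quantification, robust
k-medoids clustering of cardiac cell types, binomial cluster-enrichment
statistics, and ligand–receptor communication networks with a
source-cell-type ligand-screening funnel. This note records the models,
the defaults and why they are what they are, and the design choices made
where the method descriptions in the field leave room.

## 1. UMI-collision correction

Each captured mRNA molecule receives one of K random UMIs (6 bp ⇒
K = 4096). Counting distinct UMIs per gene removes PCR duplicates but
undercounts molecules when two molecules of the same gene draw the same
UMI. If n molecules fall uniformly and independently into K slots, the
expected number of occupied slots is K(1 − (1 − 1/K)^n); treating the
per-slot occupancy as Poisson gives the standard inversion

    n̂ = −K · ln(1 − k/K),

mapping an observed distinct-UMI count k to the expected molecule count
n̂. Properties relied on downstream: n̂(0) = 0, strict monotonicity and
convexity on [0, K), and n̂ ≥ k (collisions only hide molecules). The
inverse is undefined at k = K; saturation raises an error by default and
is clamped to K − 1 only behind an explicit flag, because silent
clamping hides data problems. Monte-Carlo occupancy simulation (tests
and acceptance script) shows the inversion recovers true molecule counts
up to 2000 with < 1 % relative bias at K = 4096.

## 2. Quantification pipeline

Order of operations: (1) remove mitochondrial genes (case-sensitive
symbol prefix `mt-`, the mouse convention; mitochondrial transcripts
dominate cardiomyocyte libraries) and blacklisted genes (`Rn45s`, a
non-polyadenylated gene whose detection is a library-prep artefact);
(2) downsample each cell's integer UMI counts to exactly T = 1000
transcripts by uniform sampling without replacement (multivariate
hypergeometric marginals), discarding cells with fewer than T;
(3) keep genes with a downsampled count ≥ 3 in ≥ 1 cell (the
`min.expr` / `min.number` filter, which is idempotent); (4) apply the
Poisson collision correction to the downsampled counts.

Downsampling requires integer input, so correction is applied last by
default; the alternative order (correct, round, then downsample) is
available behind the `order` flag. `downsample_reps` > 1 averages the
corrected matrices over several downsampling draws (RaceID-style);
the default is a single draw. All randomness flows from one integer
seed through named per-stage generators, so each stage is reproducible
in isolation.

Whether the < 1000-transcript cell filter counts raw or corrected
transcripts is an open choice; the default counts the raw downsample
total, which is the quantity the filter actually thresholds.

## 3. Distances and robust k-medoids clustering

Cell–cell distance is 1 − Pearson correlation of expression vectors
(range [0, 2], zero diagonal); zero-variance cells are an error rather
than a NaN.

**PAM.** k-medoids uses PAM: BUILD initialization followed by SWAP
steps, each taking the single best cost-reducing swap, until no swap
reduces the total distance-to-medoid. Given the distance matrix this is
deterministic; ties go to the lower index. PAM can reach genuine local
optima (on ~9 % of random ≤10-point instances in our checks — the
returned solutions admit no improving single swap, so this is the
algorithm, not a bug). `RunConfig.pam_restarts` (default 3) adds seeded
random-initialization restarts and keeps the best solution; with 10
restarts PAM matched the exhaustive-search optimum on all 600 small
instances we enumerated. No k-medoids implementation operating on a
precomputed distance matrix exists in the supporting stack, so PAM is
implemented here directly (vectorized over candidate swaps).

**Choosing k.** The within-cluster dispersion W(k) is the mean distance
over all intra-cluster cell pairs (pair-weighted pooling across
clusters; at k = 1 this is the plain mean pairwise distance). The sweep
decreases steeply while genuine structure remains — splitting removes
long cross-cluster pairs from the pool — and flattens once clusters are
internally homogeneous. The initial k is the smallest k with
(W(k) − W(k+1)) / W(k) < ε, ε = 0.05 by default. Two alternatives were
rejected: the unweighted mean over clusters of intra-cluster dispersion
is non-monotone in k, and the mean distance-to-medoid keeps improving
by > ε when splitting smooth unimodal clusters, so neither saturates
where the structure ends.

**Robustness.** Cluster stability is the mean Jaccard coefficient
between each cluster and its best-matching cluster across B = 50
bootstrap reclusterings (cells resampled with replacement, the resample
reclustered at the same k, overlap computed on the distinct cells of
the resample — `fpc::clusterboot` semantics; clusters unrepresented in
a resample are skipped for that resample). A partition is robust when
at most one cluster has mean Jaccard ≤ 0.6. Starting from the
dispersion-chosen k, k is reduced in steps of one until robustness
holds, stopping at k = 2 with the flag reported honestly. Outlier
re-assignment (as in RaceID2) is deliberately omitted. Intercluster
distance is reported as mean ± SD (ddof = 1) of pairwise medoid–medoid
distances; medoid–medoid is this package's declared definition, since
average-linkage variants are equally defensible.

## 4. Cluster enrichment and condition fold changes

**Binomial enrichment** (the `clustdiffgenes` logic): for gene g and
cluster C, p_bg is g's share of all transcripts outside C (floored at
1/(total background counts + 1) to avoid zero-probability degeneracy),
N is the total transcript count inside C, and the one-sided enrichment
p-value is P(X ≥ x) for X ~ Binomial(N, p_bg). Expected count N·p_bg
and fold x/(N·p_bg) accompany each p-value; Benjamini–Hochberg q-values
control the FDR across genes (q < 0.1 is the working threshold,
mirroring the 10 % FDR convention used downstream of such screens).
Totals are rounded to the nearest integer, so the test is exact on
integer (downsampled) matrices and an approximation on corrected ones.

Calibration: with exchangeable cells and a minority cluster (~10 % of
cells), the p < 0.05 rate stays at or below nominal (the discreteness
of the binomial tail is slightly conservative). The plug-in p_bg
ignores its own estimation error, which inflates the variance by about
(1 + N_in/N_bg); when the tested cluster is a large share of the data
(≳ 30 %) the test becomes anti-conservative (measured ~8.5 % at nominal
5 %). This is a property of the method as used in the field; the
calibration fixture therefore tests the minority-cluster regime the
test is actually used in.

**Condition fold changes** use median-of-ratios size factors (each
cell's median ratio to the gene-wise geometric mean, over genes with
non-zero geometric mean; when no gene covers every cell — common in
sparse single-cell data — total-count factors scaled to mean 1 are used
and logged). The fold change is (mean_B + c)/(mean_A + c) on normalized
group means with pseudocount c = 0.1 expected counts. A dedicated
differential-expression package is deliberately not wrapped: the ligand
funnel consumes only the ≥ 3-fold threshold, not shrinkage estimates or
p-values. The pseudocount breaks exact invariance to uniform library
scaling by O(c/mean); the invariance is exact as c → 0.

## 5. Communication networks and the ligand funnel

A gene is **expressed** by a cell type when at least τ = 20 % of the
type's cells have a count ≥ 1. The presence threshold is applied to the
expected-count matrix by default (configurable to raw counts; the
choice matters little since correction preserves zeros and near-1
counts). A ligand–receptor couple (L, R) supports the directed link
S → T iff fraction(L, S) ≥ τ and fraction(R, T) ≥ τ; autocrine loops
are allowed; the couple count per link is the edge weight. The
construction is monotone in τ and its total couple count factorizes as
Σ_pairs (#types expressing L) × (#types expressing R). Networks are
computed per condition over the types observed in that condition.
Receptor complexes are not modeled: each pair row is one ligand gene
and one receptor gene, as in compiled draft ligand–receptor lists.

The **screening funnel** for a source type (cardiomyocytes in the acute
phase): stage 1 keeps couples whose ligand the source type expresses
and whose receptor at least one type expresses; stage 2 keeps couples
whose ligand is ≥ 3-fold up-regulated in the source type, IR vs sham
(reported as a combination count and a unique-ligand count); stage 3
drops ligands on the configured extracellular-matrix list and ligands
whose expressing fraction in another type is ≥ 2× the source type's
fraction ("highly enriched elsewhere"). The 2× rule plus an explicit
ECM list is this package's auditable operationalization of what is, in
practice, a judgment call; every exclusion carries its reason, and
candidates without a fold-change entry are dropped with a logged
reason. Note the fraction-ratio rule cannot exclude a ligand whose
source-type fraction exceeds 0.5, since fractions saturate at 1.

## 6. The synthetic-data generator

The generator produces the statistical structure the pipeline exploits,
with known ground truth:

* **types and composition** — five cardiac types (CM, FB, MP, NP, EC)
  mixed per condition; the default five conditions carry the canonical
  post-infarct dynamics, with neutrophils present only in the acute
  1 dp IR condition (30 % of its cells — day-1 infarcts are
  neutrophil-rich).
* **programs** — per-gene mean weights: a shared log-normal baseline
  (σ = 1), 40 marker genes per type at 24× the baseline mean
  (neutrophil markers 3× stronger again, emulating S100a8/a9-style
  dominance), five `mt-` genes at 20× and `Rn45s` at 10× (so blacklist
  removal matters), and explicitly placed ligand/receptor genes.
* **gradients** — cardiomyocytes draw a per-cell scalar u ~ U[0, 1]
  and express (1 − u)·program + u·program_alt, where the alternative
  endpoint scales half the markers up and half down by 30 % — a
  continuous marker continuum rather than discrete subtypes.
* **counts and observation** — library size is log-normal (median
  ~2600 molecules, σ = 0.35, floored at 1500 for regular cells so that
  sub-threshold cells exist only where planted); molecule counts are
  negative-binomial (size r = 4) around the program means scaled to the
  library; each molecule then draws one of K = 4096 UMI slots uniformly
  and distinct (gene, UMI) combinations are counted. Observed ≤ true
  and observed ≤ K hold by construction, and E[observed | true = n] =
  K(1 − (1 − 1/K)^n).
* **planted communication** — four cardiomyocyte ligands with expressed
  receptors, up-regulated 5-fold under IR (one flagged ECM-like), plus
  fold-1 decoys (an expressed but unregulated CM ligand, and a
  fibroblast ligand), giving the funnel a known answer at every stage.
* **null data** — `simulate_null_dataset` collapses to one program and
  Poisson counts. Poisson (not NB) is intentional: its per-cell
  composition is multinomial, the sampling model the binomial
  enrichment test assumes, which is what a calibration fixture must
  match. With NB overdispersion the test is anti-conservative
  (section 4) — that behavior is documented, not calibrated away.

Defaults were chosen once to put the fixture in the clean-recovery
regime the planted-truth checks presuppose (separation well above
sampling noise at 1000 transcripts/cell, smallest cluster ~6 % of
cells). What passing tests show is that the pipeline recovers structure
of this kind; they do not show that real cardiac data is this clean —
real data adds doublets, ambient RNA, batch effects and cell types the
generator does not emulate.

## 7. Problem sizes and numerics

Simulated datasets are 2000 genes × 500 cells (five conditions × 100
cells), the scale at which the full pipeline — simulation,
quantification, clustering with 50 bootstrap reclusterings — runs in a
few seconds per seed; the acceptance script repeats it over 10 seeds.
Ties in PAM go to the lower index everywhere, making every clustering
call deterministic given its seed. Degenerate inputs fail loudly:
zero-variance cells, saturated UMI counts, empty backgrounds, unknown
condition labels and non-integer downsampling input all raise typed
errors (`FormatError` for on-disk problems, `ContractError` for
in-memory contract violations).

## 8. Known limitations

* Binomial enrichment is anti-conservative for clusters that are a
  large share of the dataset (section 4) and approximate on
  non-integer matrices.
* The dispersion elbow cannot resolve clusters much below ~3 % of
  cells at ε = 0.05; such populations would need the outlier machinery
  this package deliberately omits.
* The funnel's enriched-elsewhere rule saturates (section 5); the ECM
  list must be supplied by the user (`RunConfig.ecm_genes`), as ECM
  membership is curated knowledge, not derivable from counts.
* t-SNE embedding and trajectory/pseudotime analysis are out of scope;
  cluster identity never depends on an embedding.
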