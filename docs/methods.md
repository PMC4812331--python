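# Methods

## Data model and scope

The unit of input is a centroided MS/MS scan: precursor m/z, optional
charge, and a peak list. Spectra arrive one MGF file per sample; a
five-column TSV maps samples to strains, isolation-location groups,
genera and blank status. A missing CHARGE line is read as z = 1, the
dominant assumption for singly protonated [M + H]⁺ ions in
positive-mode natural-product profiling. Vendor raw formats, mzML/mzXML,
MS1 feature detection and retention-time alignment are out of scope: the
pipeline starts from peak lists.

## Peak filtering

Two filters precede all similarity computation, applied identically to
query and library spectra:

* **precursor-window exclusion** (half-width 17 Da): removes the
  unfragmented precursor and its immediate neutral-loss satellites,
  which otherwise dominate self-similarity.
* **rank-in-window filter** (top 6 per ±50 Da): a peak is kept iff fewer
  than 6 peaks within ±50 Da of its own m/z outrank it by intensity;
  intensity ties rank the lower-m/z peak first, making the result
  deterministic. Ranks are computed once on the input spectrum, not
  recomputed as peaks drop, so both filters are idempotent and a peak
  that is the intensity maximum of its own neighbourhood can never be
  removed.

## Modified cosine

Intensities are square-root transformed and the weight vector scaled to
unit Euclidean norm. Square-root weighting tempers base-peak dominance
and is the de-facto convention of molecular-networking workflows; raw
intensities remain available (`weighting="none"`), which is also the
convention the matchms cross-check in the test suite uses. Candidate
peak pairs match either directly (|Δm/z| ≤ 0.5 Da) or after shifting by
the precursor-mass difference; a pair inside both windows counts once,
as direct. The one-to-one assignment maximising the summed weight
product is found exactly with the Hungarian algorithm
(`scipy.optimize.linear_sum_assignment`). An exact matching rather than
the common greedy heuristic is a deliberate choice: greedy assignment is
measurably suboptimal on conflicting candidate sets (about 0.2% of
random 6-peak pairs in our property tests, where one large weight
product blocks two medium ones), whereas the optimal matching is
deterministic, exactly symmetric in its arguments, and provably equal to
the brute-force enumeration oracle. Scores therefore satisfy
0 ≤ s ≤ 1 and s(a, a) = 1 structurally, not approximately.

The plain (unshifted) cosine is used where near-identity is the
question — clustering replicate scans — and the shifted cosine where
analogy is the question: network edges and library search. This split is
configurable.

## Consensus clustering

Spectra sorted by precursor m/z (ties broken by spectrum id) are swept
once; each spectrum joins the lowest-numbered existing cluster whose
consensus precursor lies within 2.0 Da and whose consensus spectrum it
matches at plain cosine ≥ 0.7, otherwise it seeds a new cluster. The
cluster consensus is rebuilt after every join: pooled member peaks are
grouped single-linkage at the 0.5 Da fragment tolerance, each group
contributing one peak at the intensity-weighted mean m/z with summed
intensity, and the result re-window-filtered. The consensus precursor is
the mean of member precursors weighted by total ion intensity. This
deterministic single pass replaces the multi-round heuristics of
large-scale cluster engines; at the cohort sizes this package targets
(10³–10⁴ spectra) it recovers designed compounds exactly, and its
behaviour is fully specified, which the engines' is not. The default
minimum cluster size is 1, so no consensus spectrum is discarded.

Because consensus precursors drift as members join, a cluster member
admitted early can in principle end slightly more than the tolerance
from the final consensus; at realistic jitter (≤ 0.01 Da against a
2.0 Da tolerance) this is immaterial.

## Network construction

All unordered node pairs are scored with the shifted cosine; candidates
need cosine ≥ 0.7 **and** ≥ 6 matched peaks. Threshold comparisons are
inclusive: the workflow texts that describe these filters mix "above
0.7", "a minimum of 0.7" and "at least 6", and the inclusive reading is
the internally consistent one; both cut-offs are configurable. A
candidate edge survives iff each endpoint is among the other's top-10
candidate neighbours by cosine, with ties at the boundary all included
(a node is "in the top K" iff fewer than K neighbours score strictly
higher) — deterministic and conservative. No cap is placed on connected-
component size. Library matching uses the same shifted cosine and
thresholds against an MGF library filtered identically to the input;
all passing hits are reported with the best flagged.

## Attribution statistics

* **Media flagging**: one blank-derived member spectrum suffices to call
  a node a medium component (configurable to a higher count). This is
  deliberately conservative — anything detectable in the uninoculated
  control is discounted from strain attribution.
* **Location attribution**: a non-media node's groups are those of its
  producing samples; exactly one group ⇒ exclusive, two or more ⇒
  shared. Percentages use **all** nodes (media included) as the
  denominator, matching how such figures are reported for whole
  networks. Conservation holds by construction:
  media + Σ exclusive + shared + unattributed = total.
* **Strain specificity**: histogram of producing-strain counts per
  non-media node; the single-strain fraction is reported against all
  nodes.
* **Mass bins**: default partition 149–300 / 301–500 / 501–1000 /
  1001–2558 m/z with inclusive upper edges (300.0 falls in the first
  bin, 300.5 in the second); out-of-range nodes go to a warned overflow
  count.
* **Genus statistics**: a node counts toward every genus with ≥ 1
  producing strain; the per-strain average is count divided by the
  genus's strain count. "Cross-genus" nodes are those produced by
  strains of more than two genera (≥ 3; configurable to ≥ 2, since
  usage of the phrase is ambiguous in the literature).
* **Rounding**: all reported percentages and averages round half-up to
  one decimal (`decimal.Decimal`, not banker's rounding).
* **Rarefaction**: for k = 1..n samples, the mean and SD over seeded
  random sample orderings (default 100) of the number of distinct
  clusters seen in the first k samples; non-decreasing in k by
  construction.
* **Neutral losses**: fragment-pair mass differences are annotated
  against a built-in monoisotopic table (CO 27.99491, H₂O 18.01056,
  CO₂ 43.98983, NH₃ 17.02655 Da; extensible) at a 0.005 Da default
  tolerance, closest match winning.

## Synthetic cohorts

The generator emulates a two-location bioprospecting cohort: by default
5 strains per location plus 2 medium blanks; 25 compounds shared across
locations, 50 exclusive per location, 10 private to each strain, 6
medium components present in every sample including blanks; 10% of
compounds carry a homolog shifted by 1–3 CH₂ repeats (14.0157 Da) that
shares the parent's fragments below a random core mass and shifts the
rest, guaranteeing shifted-cosine edges by construction. Each compound
is a precursor drawn uniformly in 150–2600 Da with 8–20 fragments drawn
uniformly in (50, precursor − 20) Da — entirely below the precursor
exclusion window, so the designed ladder survives filtering — and
log-normal intensities. Every producing sample emits 3 replicate
spectra with 0.01 Da Gaussian m/z jitter, ±10% intensity noise and 3
low-intensity uniform noise peaks (about 1,500 spectra in total, a size
chosen so a full run takes seconds). A registry records each compound's
category and producing samples and maps every emitted spectrum back to
its compound.

What the generator does **not** emulate: real fragmentation chemistry,
isotope envelopes, multiply charged species, chimeric spectra,
chromatographic co-elution, and intensity correlation between
replicates. Passing recovery tests therefore demonstrates the
correctness of the clustering/attribution machinery under controlled
perturbations, not instrument-grade robustness.

Recovery is scored as: absolute error (percentage points) between
designed and recovered media/exclusive/shared fractions; cluster purity
(member-weighted largest single-compound share per node) and
completeness (spectrum-weighted largest single-node share per
compound). In the zero-jitter/zero-noise limit the pipeline's node
count equals the designed compound count and recovery is exact; at the
default noise settings recovery remains exact in practice and is
asserted within ±3 percentage points with purity ≥ 0.95.

## Determinism and degenerate inputs

All randomness (generator, rarefaction) flows from explicit integer
seeds; all orderings and tie-breaks are specified (precursor then
spectrum id for clustering; lower m/z for intensity ties; sorted node
ids for exports). Re-running a pipeline config yields byte-identical
outputs. Degenerate cases: empty spectra are retained through I/O,
flagged, and dropped after filtering; an empty library yields no hits;
an empty network exports valid header-only tables; all-zero intensity
vectors are an error at normalisation.

## Known limitations

* The greedy-pass clusterer is order-dependent by design; it is
  validated on synthetic ground truth, not against any large-scale
  engine's output.
* Pairwise node scoring is O(n²) in nodes and is sized for desk-scale
  cohorts (≲ 5,000 nodes), not repository-scale networks.
* Attribution assumes one strain per sample; pooled samples would need
  the metadata extended.
* Library search reports spectral matches only; it does not adjudicate
  isomers or adducts.
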