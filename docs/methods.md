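# Methods

This note records the modeling and design choices behind scview: what each
component computes, the defaults and why, what the synthetic data does and
does not emulate, and the numerical conventions that make results
reproducible across machines.

## The container and its persistence

A dataset is a cells × genes UMI count matrix plus a normalized expression
layer, per-cell and per-gene annotation tables, named 2-D embeddings, an
optional marker-gene table and free-text metadata. On disk it is an
AnnData-layout HDF5 file (h5ad): normalized values in `X` (CSR sparse),
counts in `layers/counts`, the cell table in `obs`, the gene table in
`var`, embeddings in `obsm` under `X_<name>`, markers in `uns/markers` and
the metadata block in `uns/about`. CSR and CSC encodings are accepted on
read; CSR is written. Cell identifiers live in the `obs` index (the
identifier column of the table under the AnnData dialect); gene display
symbols live in a `symbol` column of `var` and are made unique with
`.1`, `.2` suffixes where upstream files repeat them.

**Normalized layer.** Upstream formats disagree about whether files carry
raw counts, processed values, or both, so the container stores both when it
can: counts are always preserved when the input provides them, and the
normalized layer is derived as per-cell scaling to 10,000 total counts
followed by `log1p` — the de-facto convention of the surrounding ecosystem,
chosen so that datasets prepared elsewhere with the same convention are
directly comparable. Text inputs with non-integral values are accepted as
normalized-only (counts absent). All summaries and the differential
expression operate on the normalized layer only.

**Validation.** Validation is a report, not an exception: it returns the
full list of violated invariants (shape agreement, non-negative integer
counts, finite non-negative normalized values, unique cell identifiers and
gene symbols, two-column embeddings with one row per cell, marker cluster
labels drawn from the designated clustering column). Persistence refuses
invalid datasets and lists every violation.

**Equality contract.** Round-trip equality means: counts bit-exact,
normalized values within 1e-12 (in practice bit-exact through HDF5),
tables equal by value (categorical level *order* is not part of the
contract — different formats serialize levels in different orders),
embeddings within 1e-12, markers and metadata equal. Indices are 0-based
throughout the library surface.

## Converters

*CellRanger*: the Matrix Market triplet file is gene-major and transposed
to cells × genes; gzipped and plain inputs are equivalent. A third
`features.tsv` column, when present, restricts the matrix to
`Gene Expression` rows (other modalities would break the container
contract) with a warning. When an `analysis/` directory exists, the
canonical `clustering/graphclust/clusters.csv` and
`<tsne|umap>/2_components/projection.csv` paths are tried first, then a
single glob match; two or more candidates are an error rather than a
guess. The wide per-cluster `differential_expression.csv` is flattened to
a long (cluster, gene, log2fc, p_adj) marker table.

*loom*: the main matrix is genes × cells and transposed; row attributes
`Gene`/`Accession` become symbol/identifier, column attributes become cell
columns, and numeric `<name>_X`/`<name>_Y` pairs (case-insensitive suffix)
are assembled into embeddings. Unpaired suffixed columns stay plain
columns.

*text*: the delimiter is sniffed from the first line (tab preferred, comma
fallback). Cells are aligned between matrix and annotation by identifier —
the intersection is kept in matrix order, dropped cells are counted in the
conversion warnings, and zero overlap is an error. Annotation columns are
typed by a stated heuristic: non-numeric columns become categoricals, and
numeric columns with at most 20 distinct integral values are treated as
cluster-like categoricals (CellRanger emits cluster labels as small
integers). The threshold is a module constant, not magic scattered in
code.

## Remote sources

URLs follow an RFC 3986 subset over the schemes `file`, `http(s)`, `ftp`,
`sftp` and `s3`; scheme-less input is a local path. `user:secret`
authority parts populate a credentials field and never appear again in
canonical text, `repr`, logs or error messages. iRODS is declared in the
scheme grammar but raises an explicit not-implemented error: supporting it
requires a service dependency that cannot be exercised at desk scale, and
a visible stub is more honest than silent absence.

Retrieval goes through per-scheme transports that callers can inject
(deployments with signed S3 or SFTP credentials supply their own; tests
substitute local ones). Defaults use the standard library's HTTP/FTP
clients; S3 defaults to an unsigned path-style GET suitable for public
objects. Fetched bytes are cached under a hash of the canonical URL and
never invalidated by remote change detection — datasets are treated as
immutable artifacts, which is how this workflow uses them. Catalog listing
is shallow (no recursion) over `.h5ad` files, ordered lexicographically,
with titles read cheaply from the `uns/about` block without loading
matrices.

## Selection

Filters are conjunctions; the empty filter selects every cell. Range
predicates are inclusive on both ends, and an unknown level inside an
existing categorical column matches nothing (with a warning) rather than
erroring — a viewer user deselecting the last level expects an empty
plot, not a stack trace. Unknown *columns* and *embeddings* are errors.

Point-in-polygon membership uses even-odd ray casting with an explicit
on-segment test so that boundary points count as selected — matching the
intuitive behaviour of a box select whose edge touches a point. Boxes are
treated as their four-vertex polygons; a degenerate box selects exactly
the cells on the line. The implementation is verified against an
independent winding-number oracle on random convex polygons (where the two
definitions agree).

Manual selections that overlap are excluded from *all* groups (with the
overlap count surfaced as a warning) instead of being assigned by
selection order, so differential expression can never depend on the order
in which a user drew two lassos.

## Differential expression

The test is a two-sided Wilcoxon rank-sum on the normalized layer — the
dominant convention for two-group scRNA-seq comparisons and one that is
verifiable at the desk against exact enumeration. For tie-free samples
with total n ≤ 12 the null distribution of U is enumerated exhaustively
(at most C(12,6) = 924 assignments); otherwise the normal approximation
with tie-corrected variance and no continuity correction is used. P-values
are clamped to (0, 1]. Both branches are cross-checked in the test suite
against scipy's implementation and against an independently coded oracle.

Genes expressed (strictly positive value) in less than
`min_fraction_expressed` (default 0.1) of cells in both groups are
excluded before testing; the Benjamini–Hochberg step-up correction runs
over the m genes actually tested, so pre-filtering is part of the
procedure, not a post-hoc adjustment. Groups must have at least
`min_cells_per_group` (default 3) cells — below that a rank test is
meaningless and the error says which group is undersized.

Fold changes are computed on the de-logged scale: per-group means of
`expm1(normalized)`, then `log2((mean_A + ε)/(mean_B + ε))` with
configurable ε = 1e-9 so all-zero groups stay finite. Result rows are
sorted by ascending p, ties broken by descending |log2FC| and then by
symbol, so repeated runs serialize identically; `top_n` truncates after
sorting. Swapping the group labels negates every fold change and leaves
every p-value unchanged (tested to 1e-12).

## Summaries

"Expressing" means a strictly positive stored value throughout. Dot-plot
means are taken over *all* cells of a (group, split) combination, zeros
included — the definition under which a dot's color reflects average
expression in the population, not just in expressing cells; combinations
with no cells are omitted rather than zero-filled. Composition tables
retain zero-count primary levels (count 0, proportion 0, flagged), so bar
plots keep a stable level axis under filtering. Distribution panels
resolve a name as a gene symbol or a numeric column; a name matching both
requires an explicit `gene:`/`column:` qualifier. Quartiles use linear
interpolation — the one choice that reproduces identically across
implementations. Species-mix calls use a purity threshold (default 0.9,
configurable): a cell is assigned to a species when that species holds at
least 90% of its UMIs, and is a doublet otherwise; cells with zero total
UMIs are a domain error naming the cell. Scatter downsampling is a uniform
sample without replacement, a pure function of (n, max_points, seed).

Every summary accepts an optional cell subset and is subset-consistent:
summarizing a subset of a dataset equals summarizing the physically
subset dataset (categorical level sets are preserved under subsetting
precisely so this holds).

## Synthetic data

The generator exists to exercise every code path with known ground truth,
not to imitate any particular tissue. Counts are negative binomial with
mean `baseline_mean` (default 2) and variance `μ + φμ²` (dispersion φ,
default 0.3 — the over-dispersion range typical of droplet data), so rank
tests meet realistic zero fractions and skew. Cells are assigned to
clusters round-robin; each cluster's planted marker genes have their mean
multiplied by `fold_change` (default 4) in that cluster's cells, and the
marker table is filled from this truth. The default study conditions used
by the acceptance checks are 100 cells per group, 200 genes, 10 planted
markers per cluster at 4-fold change, and a null variant at fold change 1.

The 2-D "tsne" embedding is cluster centroids on a circle of radius 10
with unit Gaussian spread — deliberately *not* a real manifold embedding;
the viewer only needs coordinates with visible cluster structure. The
species-mix generator draws per-cell doublet status Bernoulli(rate),
assigns singlets 1:1 between species, gives each singlet Poisson(mean)
own-species UMIs plus 1% ambient contamination from the other species, and
sums two opposite-species singlets for a doublet. At the default depth
(5,000 UMIs) singlet purity is ≈0.99 and doublet purity ≈0.5, so the 0.9
threshold reproduces the planted calls exactly; what the recovery test
then measures is the binomial sampling of the rate itself.

Passing tests on these data therefore demonstrate correctness of the
machinery — round trips, test calibration under a known null,
planted-effect recovery — but not robustness to batch effects, cell-cycle
structure, ambient RNA beyond the fixed 1%, or real embedding geometry,
none of which are simulated.

## Service and CLI

The HTTP service is a thin stateless layer over the library: every numeric
payload is produced by the corresponding library call and serialized
(JSON for structures, TSV for tables), and the test suite asserts
byte-equality between served payloads and direct calls. Datasets load
lazily; a source that fails to load appears in the catalog with its error
instead of aborting startup. Uploads are size-capped (default 512 MiB) and
validated before cataloging. Figure rendering is left to whatever plotting
front-end consumes the payloads — only the data contract is part of this
package.

Sources come from repeated `--data-source` flags or the
`SCVIEW_DATA_SOURCES` environment variable (semicolon-separated); flags
win on conflict. Defaults when a view needs one: the lexicographically
first embedding and the first categorical column.

## Known limitations

- Whole-file loading only: no backed/on-disk matrices, no multi-modal
  (CITE-seq/ATAC) layers.
- No pseudobulk, covariate-adjusted or mixed-model differential
  expression, and no gene-set enrichment.
- SFTP and credentialed S3 require caller-supplied transports; iRODS is a
  stub.
- The rank-sum exact branch is limited to n ≤ 12 without ties; beyond
  that the normal approximation is used even where a larger exact
  computation would be feasible.
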