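# HTTP API

All endpoints live under `/api`. Request bodies are JSON; tabular
responses are TSV (`text/tab-separated-values`), structural responses are
JSON. Errors return a JSON object `{"error": "<message>"}` with status
400 (404 for unknown routes).

## Catalog and dataset views

### `GET /api/catalog`

List the configured datasets.

```json
[
  {"id": "demo", "source": "/data/demo.h5ad",
   "title": "synthetic clustered dataset", "short": "300 cells, ..."},
  {"source": "s3://bucket/missing.h5ad", "error": "..."}
]
```

Sources that failed to list or load are reported with an `error` key.

### `GET /api/dataset/<id>/about`

```json
{"title": "...", "short": "...", "long": "markdown text"}
```

### `GET /api/dataset/<id>/meta`

Dimensions, cell-table columns with their kinds and levels, embedding
names, gene symbols, marker-gene pick-list and the designated clustering
column:

```json
{"n_cells": 300, "n_genes": 200,
 "columns": {"cluster": {"kind": "categorical", "levels": ["1","2","3"]},
             "n_counts": {"kind": "numeric"}},
 "embeddings": ["tsne"], "genes": ["G0000", "..."],
 "marker_genes": ["G0000", "..."], "cluster_column": "cluster"}
```

### `GET /api/dataset/<id>/markers`

The marker table as TSV (columns as stored: `cluster`, `gene`, plus any
score columns).

### `GET /api/dataset/<id>/scatter?embedding=<name>&max_points=<n>&seed=<s>`

Downsampled embedding coordinates. Defaults: first embedding
(lexicographic), the service's `max_scatter_points`, seed 0.

```json
{"embedding": "tsne", "cells": [0, 2, 5], "x": [...], "y": [...]}
```

## Selection and analysis

### `POST /api/dataset/<id>/filter`

Body: `{"filter": <FilterSpec>}` where FilterSpec is a list of predicate
objects combined conjunctively:

```json
[
  {"type": "categorical", "column": "cluster", "levels": ["1", "3"]},
  {"type": "range", "column": "n_counts", "low": 500, "high": null},
  {"type": "region", "embedding": "tsne", "box": [-10, 10, -10, 10]},
  {"type": "region", "embedding": "tsne",
   "polygon": [[0, 0], [5, 0], [5, 5]]}
]
```

Response: `{"cells": [0-based indices]}`.

### `POST /api/dataset/<id>/diffexp`

Body:

```json
{"groups": {"A": [0, 1, 2], "B": [10, 11, 12]},
 "params": {"min_cells_per_group": 3, "min_fraction_expressed": 0.1,
            "top_n": null}}
```

`params` is optional. Response: TSV with columns
`symbol  statistic  p  p_adj  log2fc  mean_a  mean_b  frac_a  frac_b`,
sorted by ascending p (ties: descending |log2fc|, then symbol). The
response is byte-identical to the library's
`differential_expression(...).to_tsv()`.

### `POST /api/dataset/<id>/summary/dotplot`

Body: `{"genes": [...], "group_by": "cluster", "split_by": "condition",
"cells": [...]}` (`split_by`, `cells` optional). Response: TSV with
columns `group [split] gene mean fraction`.

### `POST /api/dataset/<id>/summary/composition`

Body: `{"primary": "cluster", "secondary": "condition", "cells": [...]}`.
Response: TSV with per-primary-level `count_<level>` and `prop_<level>`
columns.

### `POST /api/dataset/<id>/summary/distribution`

Body: `{"value": "G0001", "group_by": "cluster", "cells": [...]}`.
`value` is a gene symbol or numeric column; qualify as `gene:NAME` /
`column:NAME` when ambiguous. Response: TSV with columns
`group count median q1 q3`.

## Uploads

### `POST /api/upload?name=<id>`

Raw h5ad bytes as the request body. The file is validated before being
cataloged; the response is `{"id": "<assigned id>"}` (status 201), with a
`-1`, `-2` suffix appended when the requested name is taken.
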