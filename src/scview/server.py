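"""Lightweight HTTP service exposing the library over a JSON/TSV API.

The service is a thin stateless layer: every numeric payload is produced by
the corresponding library call (filtering, differential expression,
summaries) and serialized — the service adds no computation of its own.
Datasets are resolved lazily from the configured sources; sources that fail
to load are reported in the catalog instead of aborting startup. Uploaded
h5ad files are validated and added to the catalog under a fresh identifier.

Endpoints (request/response schemas in docs/api.md):

==========================================  ======================================
``GET  /api/catalog``                       catalog entries as JSON
``GET  /api/dataset/<id>/about``            title/short/long JSON
``GET  /api/dataset/<id>/meta``             columns, embeddings, genes, markers
``GET  /api/dataset/<id>/markers``          marker table as TSV
``GET  /api/dataset/<id>/scatter``          downsampled embedding coords JSON
``POST /api/dataset/<id>/filter``           FilterSpec JSON -> cell indices
``POST /api/dataset/<id>/diffexp``          groups+params JSON -> DE table TSV
``POST /api/dataset/<id>/summary/dotplot``  genes/group_by JSON -> TSV
``POST /api/dataset/<id>/summary/composition``  primary/secondary JSON -> TSV
``POST /api/dataset/<id>/summary/distribution`` value/group_by JSON -> TSV
``POST /api/upload?name=<id>``              raw h5ad body -> catalog entry
==========================================  ======================================
"""

from __future__ import annotations

import json
import threading
import urllib.parse
from dataclasses import dataclass, field
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from pathlib import Path

import numpy as np
import pandas as pd

from . import summaries
from .dataset import CellDataset, load_dataset_file
from .diffexp import DiffExpParams, differential_expression
from .errors import ScviewError, SourceError
from .select import FilterSpec, GroupAssignment, apply_filter
from .sources import SourceURL, fetch_dataset, list_catalog, parse_source_url

__all__ = ["AppConfig", "AppState", "run_server", "start_server"]

DEFAULT_MAX_SCATTER_POINTS = 50_000
DEFAULT_UPLOAD_CAP_BYTES = 512 * 1024 * 1024


@dataclass
class AppConfig:
    """Service configuration (CLI flags / environment variable backed)."""

    data_sources: list[SourceURL] = field(default_factory=list)
    cache_dir: Path = Path(".scview-cache")
    host: str = "127.0.0.1"
    port: int = 8050
    max_scatter_points: int = DEFAULT_MAX_SCATTER_POINTS
    upload_enabled: bool = True
    conversion_enabled: bool = True
    upload_cap_bytes: int = DEFAULT_UPLOAD_CAP_BYTES

    def validate(self) -> None:
        if not self.data_sources and not self.upload_enabled:
            raise ScviewError("need at least one data source or uploads enabled")
        if not (0 <= self.port < 65536):  # 0 requests an ephemeral port
            raise ScviewError(f"port out of range: {self.port}")


class AppState:
    """Catalog plus lazily loaded dataset cache behind the endpoints."""

    def __init__(self, config: AppConfig):
        config.validate()
        self.config = config
        self.sources: dict[str, SourceURL] = {}
        self.errors: dict[str, str] = {}
        self._cache: dict[str, CellDataset] = {}
        self._lock = threading.Lock()
        for url in config.data_sources:
            self._register_source(url)

    def _register_source(self, url: SourceURL) -> None:
        if url.scheme == "file" and Path(url.path).is_dir():
            try:
                catalog = list_catalog(url)
            except SourceError as exc:
                self.errors[url.render()] = str(exc)
                return
            for entry in catalog.entries:
                self.sources[entry.identifier] = entry.source
        else:
            stem = Path(urllib.parse.urlparse(url.render()).path or url.path).stem
            identifier = stem or url.render()
            self.sources[self._fresh_id(identifier)] = url

    def _fresh_id(self, base: str) -> str:
        if base not in self.sources:
            return base
        k = 1
        while f"{base}-{k}" in self.sources:
            k += 1
        return f"{base}-{k}"

    def catalog(self) -> list[dict]:
        out = []
        for identifier in sorted(self.sources):
            entry = {"id": identifier, "source": self.sources[identifier].render()}
            try:
                ds = self.dataset(identifier)
                entry["title"] = ds.about.title
                entry["short"] = ds.about.short
            except ScviewError as exc:
                entry["error"] = str(exc)
            out.append(entry)
        for source, message in self.errors.items():
            out.append({"source": source, "error": message})
        return out

    def dataset(self, identifier: str) -> CellDataset:
        with self._lock:
            if identifier not in self._cache:
                if identifier not in self.sources:
                    raise ScviewError(f"unknown dataset {identifier!r}")
                self._cache[identifier] = fetch_dataset(
                    self.sources[identifier], self.config.cache_dir
                )
            return self._cache[identifier]

    def add_upload(self, name: str, payload: bytes) -> str:
        if not self.config.upload_enabled:
            raise ScviewError("uploads are disabled")
        if len(payload) > self.config.upload_cap_bytes:
            raise ScviewError("upload exceeds the size cap")
        upload_dir = Path(self.config.cache_dir) / "uploads"
        upload_dir.mkdir(parents=True, exist_ok=True)
        identifier = self._fresh_id(name or "upload")
        target = upload_dir / f"{identifier}.h5ad"
        target.write_bytes(payload)
        load_dataset_file(target)  # validate before cataloging
        self.sources[identifier] = SourceURL(scheme="file", path=str(target))
        return identifier


# ----------------------------------------------------------------------
# request handling


def _groups_from_payload(payload: dict) -> GroupAssignment:
    groups = {
        label: set(int(i) for i in cells)
        for label, cells in payload.get("groups", {}).items()
    }
    return GroupAssignment(groups=groups)


class _Handler(BaseHTTPRequestHandler):
    state: AppState  # injected by make_server

    # silence per-request stderr logging
    def log_message(self, fmt, *args):
        pass

    def _send(self, status: int, body: bytes, content_type: str) -> None:
        self.send_response(status)
        self.send_header("Content-Type", content_type)
        self.send_header("Content-Length", str(len(body)))
        self.end_headers()
        self.wfile.write(body)

    def _json(self, obj, status: int = 200) -> None:
        self._send(status, json.dumps(obj).encode(), "application/json")

    def _tsv(self, text: str) -> None:
        self._send(200, text.encode(), "text/tab-separated-values")

    def _error(self, exc: Exception, status: int = 400) -> None:
        self._json({"error": str(exc)}, status=status)

    # -- GET ------------------------------------------------------------
    def do_GET(self):
        parsed = urllib.parse.urlparse(self.path)
        parts = [p for p in parsed.path.split("/") if p]
        query = urllib.parse.parse_qs(parsed.query)
        try:
            if parsed.path == "/":
                self._send(200, b"<html><body>scview service</body></html>", "text/html")
            elif parts == ["api", "catalog"]:
                self._json(self.state.catalog())
            elif len(parts) == 4 and parts[:2] == ["api", "dataset"]:
                ds = self.state.dataset(parts[2])
                view = parts[3]
                if view == "about":
                    self._json(
                        {"title": ds.about.title, "short": ds.about.short,
                         "long": ds.about.long}
                    )
                elif view == "meta":
                    self._json(_meta_payload(ds))
                elif view == "markers":
                    self._tsv(ds.markers.to_csv(sep="\t", index=False))
                elif view == "scatter":
                    self._json(_scatter_payload(ds, query, self.state.config))
                else:
                    self._json({"error": f"unknown view {view!r}"}, status=404)
            else:
                self._json({"error": "not found"}, status=404)
        except ScviewError as exc:
            self._error(exc)

    # -- POST -----------------------------------------------------------
    def do_POST(self):
        parsed = urllib.parse.urlparse(self.path)
        parts = [p for p in parsed.path.split("/") if p]
        length = int(self.headers.get("Content-Length", 0))
        body = self.rfile.read(length)
        try:
            if parts == ["api", "upload"]:
                query = urllib.parse.parse_qs(parsed.query)
                name = query.get("name", ["upload"])[0]
                identifier = self.state.add_upload(name, body)
                self._json({"id": identifier}, status=201)
                return
            if len(parts) < 4 or parts[:2] != ["api", "dataset"]:
                self._json({"error": "not found"}, status=404)
                return
            ds = self.state.dataset(parts[2])
            payload = json.loads(body.decode() or "{}")
            action = parts[3]
            if action == "filter":
                cells = apply_filter(
                    ds, FilterSpec.from_json(json.dumps(payload.get("filter", [])))
                )
                self._json({"cells": sorted(cells)})
            elif action == "diffexp":
                params = DiffExpParams(**payload.get("params", {}))
                result = differential_expression(
                    ds, _groups_from_payload(payload), params
                )
                self._tsv(result.to_tsv())
            elif action == "summary" and len(parts) == 5:
                self._tsv(_summary_payload(ds, parts[4], payload))
            else:
                self._json({"error": f"unknown action {action!r}"}, status=404)
        except ScviewError as exc:
            self._error(exc)
        except (ValueError, KeyError, TypeError) as exc:
            self._error(exc)


def _meta_payload(ds: CellDataset) -> dict:
    columns = {}
    for col in ds.cell_table.columns:
        series = ds.cell_table[col]
        if isinstance(series.dtype, pd.CategoricalDtype):
            columns[col] = {
                "kind": "categorical",
                "levels": [str(c) for c in series.cat.categories],
            }
        else:
            columns[col] = {"kind": "numeric"}
    return {
        "n_cells": ds.n_cells,
        "n_genes": ds.n_genes,
        "columns": columns,
        "embeddings": sorted(ds.embeddings),
        "genes": ds.gene_table["symbol"].tolist(),
        "marker_genes": sorted(set(ds.markers["gene"].astype(str)))
        if len(ds.markers)
        else [],
        "cluster_column": ds.cluster_column,
    }


def _scatter_payload(ds: CellDataset, query: dict, config: AppConfig) -> dict:
    names = sorted(ds.embeddings)
    if not names:
        raise ScviewError("dataset has no embedding")
    name = query.get("embedding", [names[0]])[0]
    if name not in ds.embeddings:
        raise ScviewError(f"unknown embedding {name!r}")
    max_points = int(query.get("max_points", [config.max_scatter_points])[0])
    seed = int(query.get("seed", [0])[0])
    keep = sorted(summaries.downsample_cells(ds.n_cells, max_points, seed))
    coords = np.asarray(ds.embeddings[name])[keep]
    return {
        "embedding": name,
        "cells": keep,
        "x": coords[:, 0].tolist(),
        "y": coords[:, 1].tolist(),
    }


def _summary_payload(ds: CellDataset, kind: str, payload: dict) -> str:
    cells = payload.get("cells")
    if kind == "dotplot":
        return summaries.dot_plot_summary(
            ds,
            payload["genes"],
            payload["group_by"],
            split_by=payload.get("split_by"),
            cells=cells,
        ).to_tsv()
    if kind == "composition":
        return summaries.composition_table(
            ds, payload["primary"], payload["secondary"], cells=cells
        ).to_tsv()
    if kind == "distribution":
        return summaries.distribution_panel(
            ds, payload["value"], payload["group_by"], cells=cells
        ).to_tsv()
    raise ScviewError(f"unknown summary kind {kind!r}")


# ----------------------------------------------------------------------
# lifecycle


def make_server(config: AppConfig) -> ThreadingHTTPServer:
    state = AppState(config)
    handler = type("BoundHandler", (_Handler,), {"state": state})
    try:
        server = ThreadingHTTPServer((config.host, config.port), handler)
    except OSError as exc:
        raise ScviewError(f"cannot bind {config.host}:{config.port}: {exc}") from exc
    return server


def start_server(config: AppConfig) -> ThreadingHTTPServer:
    """Start the service in a background thread; caller must ``shutdown()``."""
    server = make_server(config)
    thread = threading.Thread(target=server.serve_forever, daemon=True)
    thread.start()
    return server


def run_server(config: AppConfig) -> None:
    """Run the service in the foreground until interrupted."""
    server = make_server(config)
    try:
        server.serve_forever()
    finally:
        server.server_close()
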