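"""Dataset source resolution: URL parsing, retrieval with caching, catalogs.

Datasets can live on the local file system or behind ``http(s)``, ``ftp``,
``sftp`` or ``s3`` locators. Remote bytes are fetched through per-scheme
transports (injectable, so tests and deployments can substitute their own),
cached under a content-address derived from the canonical URL, and loaded
through the regular h5ad reader. Credentials embedded in a URL are parsed
out and never reappear in canonical text, logs or error messages.
"""

from __future__ import annotations

import hashlib
import urllib.error
import urllib.parse
import urllib.request
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional

import h5py

from .dataset import CellDataset, load_dataset_file
from .errors import (
    FormatError,
    NotImplementedSchemeError,
    SourceError,
    UnsupportedSchemeError,
)

__all__ = [
    "SourceURL",
    "CatalogEntry",
    "DatasetCatalog",
    "parse_source_url",
    "fetch_dataset",
    "list_catalog",
]

SUPPORTED_SCHEMES = ("file", "http", "https", "ftp", "sftp", "s3")


@dataclass(frozen=True)
class SourceURL:
    """Parsed data-source locator."""

    scheme: str
    host: str = ""
    port: Optional[int] = None
    path: str = ""
    credentials: Optional[tuple[str, str]] = None

    def render(self) -> str:
        """Canonical text form — credentials are always stripped."""
        if self.scheme == "file":
            return self.path
        netloc = self.host
        if self.port is not None:
            netloc = f"{netloc}:{self.port}"
        return f"{self.scheme}://{netloc}{self.path}"

    def __str__(self) -> str:
        return self.render()

    def __repr__(self) -> str:  # never leak secrets via repr
        return f"SourceURL({self.render()!r})"


@dataclass
class CatalogEntry:
    identifier: str
    source: SourceURL
    title: str = ""
    short: str = ""


@dataclass
class DatasetCatalog:
    entries: list[CatalogEntry]

    def __post_init__(self) -> None:
        ids = [e.identifier for e in self.entries]
        if len(set(ids)) != len(ids):
            raise SourceError(f"duplicate dataset identifiers in catalog: {ids}")


def parse_source_url(text: str) -> SourceURL:
    """Parse a locator string; scheme-less input is a local file path.

    ``user:secret@host`` authority parts populate ``credentials`` and are
    removed from the canonical form.
    """
    text = str(text)
    if "://" not in text:
        return SourceURL(scheme="file", path=text)
    parts = urllib.parse.urlsplit(text)
    scheme = parts.scheme.lower()
    if scheme == "irods":
        raise NotImplementedSchemeError(
            "the iRODS protocol is declared but not implemented in this build"
        )
    if scheme not in SUPPORTED_SCHEMES:
        raise UnsupportedSchemeError(f"unsupported URL scheme: {scheme!r}")
    credentials = None
    if parts.username is not None:
        credentials = (parts.username, parts.password or "")
    if scheme == "file":
        return SourceURL(scheme="file", path=parts.path)
    path = parts.path or "/"
    return SourceURL(
        scheme=scheme,
        host=parts.hostname or "",
        port=parts.port,
        path=path,
        credentials=credentials,
    )


# ----------------------------------------------------------------------
# transports

Transport = Callable[[SourceURL], bytes]


def _http_transport(url: SourceURL) -> bytes:
    with urllib.request.urlopen(url.render()) as resp:
        return resp.read()


def _ftp_transport(url: SourceURL) -> bytes:
    rendered = url.render()
    if url.credentials is not None:
        user, secret = url.credentials
        netloc = f"{urllib.parse.quote(user)}:{urllib.parse.quote(secret)}@{url.host}"
        if url.port is not None:
            netloc += f":{url.port}"
        rendered = f"ftp://{netloc}{url.path}"
    with urllib.request.urlopen(rendered) as resp:
        return resp.read()


def _s3_transport(url: SourceURL) -> bytes:
    # unsigned path-style GET against public buckets; signed access needs an
    # injected transport
    if url.credentials is not None:
        raise SourceError(
            "credentialed S3 access requires an injected transport "
            f"(s3://{url.host}{url.path})"
        )
    endpoint = f"https://{url.host}.s3.amazonaws.com{url.path}"
    with urllib.request.urlopen(endpoint) as resp:
        return resp.read()


def _sftp_transport(url: SourceURL) -> bytes:
    raise SourceError(
        "no SFTP client is configured; inject a transport for scheme 'sftp' "
        f"(sftp://{url.host}{url.path})"
    )


DEFAULT_TRANSPORTS: dict[str, Transport] = {
    "http": _http_transport,
    "https": _http_transport,
    "ftp": _ftp_transport,
    "s3": _s3_transport,
    "sftp": _sftp_transport,
}


def cache_path_for(url: SourceURL, cache_dir) -> Path:
    digest = hashlib.sha256(url.render().encode()).hexdigest()[:24]
    return Path(cache_dir) / f"{digest}.h5ad"


def fetch_dataset(
    url: SourceURL, cache_dir, transport: Optional[Transport] = None
) -> CellDataset:
    """Retrieve a dataset's bytes, cache them, and load the container.

    Local ``file`` URLs open directly. Remote URLs go through the scheme's
    transport once; later fetches of the same canonical URL are served from
    the cache without touching the transport.
    """
    if url.scheme == "file":
        return load_dataset_file(url.path)
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    target = cache_path_for(url, cache_dir)
    if not target.is_file():
        transport = transport or DEFAULT_TRANSPORTS[url.scheme]
        try:
            payload = transport(url)
        except (SourceError, FormatError):
            raise
        except Exception as exc:
            raise SourceError(
                f"failed to retrieve {url.render()} ({url.scheme}): {exc}"
            ) from exc
        tmp = target.with_suffix(".part")
        tmp.write_bytes(payload)
        tmp.rename(target)
    try:
        return load_dataset_file(target)
    except FormatError:
        target.unlink(missing_ok=True)  # do not cache junk
        raise


# ----------------------------------------------------------------------
# catalogs


def _cheap_about(path: Path) -> tuple[str, str]:
    """Read title/short from an h5ad's uns block without loading matrices."""
    try:
        with h5py.File(path, "r") as f:
            about = f.get("uns/about")
            if about is None:
                return path.stem, ""
            title = about["title"][()] if "title" in about else b""
            short = about["short"][()] if "short" in about else b""
            decode = lambda v: v.decode() if isinstance(v, bytes) else str(v)
            return decode(title) or path.stem, decode(short)
    except OSError:
        return path.stem, ""


def list_catalog(url: SourceURL) -> DatasetCatalog:
    """Enumerate the ``.h5ad`` datasets under a directory locator.

    Entries are ordered lexicographically by identifier (the file stem);
    titles come from each file's about block when cheaply readable.
    """
    if url.scheme != "file":
        raise SourceError(
            f"catalog listing is only supported for local folders, not {url.scheme}"
        )
    folder = Path(url.path)
    if not folder.is_dir():
        raise SourceError(f"not a listable folder: {folder}")
    entries = []
    for child in sorted(folder.iterdir(), key=lambda p: p.stem):
        if child.suffix == ".h5ad" and child.is_file():
            title, short = _cheap_about(child)
            entries.append(
                CatalogEntry(
                    identifier=child.stem,
                    source=SourceURL(scheme="file", path=str(child)),
                    title=title,
                    short=short,
                )
            )
    seen = set()
    for e in entries:
        if e.identifier in seen:
            warnings.warn(f"duplicate dataset identifier {e.identifier!r} in catalog")
        seen.add(e.identifier)
    return DatasetCatalog(entries=entries)
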