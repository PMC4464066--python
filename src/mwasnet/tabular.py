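"""Reading and writing the tool's file formats.

Feature tables, target-metabolite lists and class labels are plain
tab-delimited text; networks are exported as Cytoscape-compatible GML;
every run is described by a JSON manifest that records options, input
hashes and outputs so an analysis can be reproduced from the manifest
alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd


class FormatError(ValueError):
    """A file does not conform to the tab-delimited input contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """m/z + retention-time keyed matrix of per-sample ion intensities.

    Parameters
    ----------
    mz : array of mass-to-charge values (Th), one per feature.
    rt : array of retention times (seconds), one per feature.
    intensities : 2-D array, features x samples; NaN marks missing.
    sample_ids : ordered sample labels (unique).
    feature_ids : canonical labels ``"<mz>_<rt>"`` with m/z rounded to 4
        decimals and rt to 0; duplicates receive an ordinal suffix.
    """

    mz: np.ndarray
    rt: np.ndarray
    intensities: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        n = len(self.mz)
        if not (len(self.rt) == n == self.intensities.shape[0]):
            raise ValueError("mz, rt and intensity rows must have equal length")
        if self.intensities.shape[1] != len(self.sample_ids):
            raise ValueError("intensity columns must match sample_ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")
        if np.nanmin(self.intensities, initial=0.0) < 0:
            raise ValueError("negative intensities are not allowed")
        if np.any(self.mz <= 0):
            raise ValueError("m/z values must be positive")
        if np.any(self.rt < 0):
            raise ValueError("retention times must be non-negative")
        if not self.feature_ids:
            self.feature_ids = make_feature_ids(self.mz, self.rt)
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("feature_ids must be unique")

    @property
    def n_features(self) -> int:
        return len(self.mz)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        """Tab-file layout: mz, time, then one intensity column per sample."""
        df = pd.DataFrame({"mz": self.mz, "time": self.rt})
        for j, sid in enumerate(self.sample_ids):
            df[sid] = self.intensities[:, j]
        return df

    def subset(self, idx: Sequence[int]) -> "FeatureTable":
        idx = np.asarray(idx, dtype=int)
        return FeatureTable(
            mz=self.mz[idx],
            rt=self.rt[idx],
            intensities=self.intensities[idx, :],
            sample_ids=list(self.sample_ids),
            feature_ids=[self.feature_ids[i] for i in idx],
        )

    def subset_samples(self, cols: Sequence[int]) -> "FeatureTable":
        cols = list(cols)
        return FeatureTable(
            mz=self.mz.copy(),
            rt=self.rt.copy(),
            intensities=self.intensities[:, cols],
            sample_ids=[self.sample_ids[j] for j in cols],
            feature_ids=list(self.feature_ids),
        )


def make_feature_ids(mz: np.ndarray, rt: np.ndarray) -> list[str]:
    """Canonical display ids "mz_rt" (4 / 0 decimals), deduplicated."""
    ids: list[str] = []
    seen: dict[str, int] = {}
    for m, t in zip(mz, rt):
        base = f"{m:.4f}_{t:.0f}"
        if base in seen:
            seen[base] += 1
            ids.append(f"{base}.{seen[base]}")
        else:
            seen[base] = 0
            ids.append(base)
    return ids


@dataclass(frozen=True)
class TargetQuery:
    """A targeted metabolite: query mass, optional retention time, label."""

    mz: float
    rt: Optional[float] = None
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("query m/z must be positive")
        if self.rt is not None and self.rt < 0:
            raise ValueError("query retention time must be non-negative")

    @property
    def label(self) -> str:
        if self.name:
            return self.name
        if self.rt is not None:
            return f"{self.mz:.4f}_{self.rt:.0f}"
        return f"{self.mz:.4f}"


@dataclass
class RunManifest:
    """Provenance record for one run: options, inputs (hashed), outputs, seed."""

    tool_version: str
    command: str
    options: dict[str, Any]
    input_files: dict[str, Optional[str]] = field(default_factory=dict)
    input_hashes: dict[str, Optional[str]] = field(default_factory=dict)
    output_files: list[str] = field(default_factory=list)
    seed: Optional[int] = None
    timestamp: Optional[str] = None

    def add_input(self, role: str, path: Optional[str]) -> None:
        self.input_files[role] = path
        self.input_hashes[role] = sha256_file(path) if path else None

    def equivalent(self, other: "RunManifest") -> bool:
        """Equality ignoring timestamps (the determinism contract)."""
        a = dataclasses.asdict(self)
        b = dataclasses.asdict(other)
        a.pop("timestamp")
        b.pop("timestamp")
        return a == b


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# tab-delimited readers / writers
# ---------------------------------------------------------------------------

_NA_STRINGS = {"", "NA", "na", "NaN", "nan"}


def _parse_float(cell: str) -> float:
    cell = cell.strip()
    if cell in _NA_STRINGS:
        return np.nan
    return float(cell)


def read_feature_table(path: str | Path, lenient: bool = False) -> FeatureTable:
    """Read a tab-delimited feature table.

    The first two columns are m/z and retention time; every remaining
    column is one sample's intensity profile. A header row is required.
    Empty cells and "NA" become missing intensities. With ``lenient``
    rows with a malformed m/z or time are dropped instead of raising.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() != ""]
    if len(lines) < 2:
        raise FormatError(f"{path}: need a header row and at least one data row")
    header = lines[0].split("\t")
    if len(header) < 3:
        raise FormatError(
            f"{path}: feature table needs >= 3 columns (m/z, time, samples); "
            f"got {len(header)}"
        )
    sample_ids = [h.strip() for h in header[2:]]
    if len(set(sample_ids)) != len(sample_ids):
        dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise FormatError(f"{path}: duplicate sample headers: {dupes}")

    mz, rt, rows = [], [], []
    n_errored = 0
    for lineno, ln in enumerate(lines[1:], start=2):
        cells = ln.split("\t")
        if len(cells) != len(header):
            cells = cells + [""] * (len(header) - len(cells))
        try:
            m = float(cells[0])
            t = float(cells[1])
        except ValueError:
            if lenient:
                n_errored += 1
                continue
            raise FormatError(
                f"{path}: line {lineno}: m/z and time must be numeric "
                f"(got {cells[0]!r}, {cells[1]!r})"
            )
        intens = []
        for c in cells[2:]:
            try:
                intens.append(_parse_float(c))
            except ValueError:
                intens.append(np.nan)  # non-numeric intensity cell -> missing
        mz.append(m)
        rt.append(t)
        rows.append(intens)
    if not rows:
        raise FormatError(f"{path}: no parseable data rows")
    return FeatureTable(
        mz=np.array(mz),
        rt=np.array(rt),
        intensities=np.array(rows, dtype=float),
        sample_ids=sample_ids,
    )


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write the standard tab-delimited layout; missing values as empty cells."""
    with open(path, "w") as fh:
        fh.write("mz\ttime\t" + "\t".join(table.sample_ids) + "\n")
        for i in range(table.n_features):
            cells = [f"{table.mz[i]:.6f}", f"{table.rt[i]:.2f}"]
            for v in table.intensities[i, :]:
                cells.append("" if np.isnan(v) else repr(float(v)))
            fh.write("\t".join(cells) + "\n")


def read_target_list(path: str | Path) -> list[TargetQuery]:
    """Read the target-metabolite list: m/z, optional rt, optional name.

    A header row is detected (non-numeric first cell on line 1) and
    skipped; every other row must begin with a numeric m/z.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() != ""]
    if not lines:
        raise FormatError(f"{path}: target list is empty")

    start = 0
    if len(lines) > 1:
        try:
            float(lines[0].split("\t")[0])
        except ValueError:
            start = 1  # header row
    queries: list[TargetQuery] = []
    for rowno, ln in enumerate(lines[start:], start=start + 1):
        cells = [c.strip() for c in ln.split("\t")]
        try:
            mz = float(cells[0])
        except ValueError:
            raise FormatError(f"{path}: row {rowno}: non-numeric m/z {cells[0]!r}")
        rt = None
        if len(cells) > 1 and cells[1] not in _NA_STRINGS:
            try:
                rt = float(cells[1])
            except ValueError:
                raise FormatError(f"{path}: row {rowno}: non-numeric rt {cells[1]!r}")
        name = cells[2] if len(cells) > 2 and cells[2] else None
        queries.append(TargetQuery(mz=mz, rt=rt, name=name))
    if not queries:
        raise FormatError(f"{path}: target list has no data rows")
    return queries


def read_class_labels(path: str | Path, sample_ids: Sequence[str] | None = None) -> dict[str, str]:
    """Read sample -> class mapping (tab-delimited: sample_id, label).

    A single-column file is interpreted as labels in feature-table
    sample order, in which case ``sample_ids`` is required.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() != ""]
    if not lines:
        raise FormatError(f"{path}: class-labels file is empty")
    rows = [ln.split("\t") for ln in lines]
    if all(len(r) >= 2 for r in rows):
        if rows[0][0].lower() in {"sample", "sample_id", "sampleid"}:
            rows = rows[1:]
        mapping = {r[0].strip(): r[1].strip() for r in rows}
    else:
        if sample_ids is None:
            raise FormatError(
                f"{path}: single-column class labels need the feature table's sample order"
            )
        labels = [r[0].strip() for r in rows]
        if len(labels) != len(sample_ids):
            raise FormatError(
                f"{path}: {len(labels)} labels for {len(sample_ids)} samples"
            )
        mapping = dict(zip(sample_ids, labels))
    if sample_ids is not None:
        missing = [s for s in sample_ids if s not in mapping]
        if missing:
            raise FormatError(f"{path}: no class label for samples {missing}")
    return mapping


def read_mz_list(path: str | Path) -> list[float]:
    """Read a one-column list of m/z values (e.g. significant features)."""
    return [q.mz for q in read_target_list(path)]


# ---------------------------------------------------------------------------
# GML
# ---------------------------------------------------------------------------

def write_gml(network, path: str | Path) -> None:
    """Export an association network as plain Cytoscape-compatible GML.

    Nodes get integer ids plus label/mz/rt/is_seed/depth attributes;
    edges carry weight (the signed correlation), qvalue and depth.
    """
    g = network.graph if hasattr(network, "graph") else network
    out = nx.Graph()
    order = list(g.nodes())
    if len(set(order)) != len(order):
        raise ValueError("node ids must be unique")
    # string-named nodes: networkx assigns integer ids and writes the
    # name as the GML label, which Cytoscape displays
    for node in order:
        d = g.nodes[node]
        out.add_node(
            str(node),
            mz=float(d.get("mz", 0.0)),
            rt=float(d.get("rt", 0.0)),
            is_seed=int(bool(d.get("is_seed", False))),
            depth=int(d.get("depth", 0)),
        )
    for u, v, d in g.edges(data=True):
        out.add_edge(
            str(u),
            str(v),
            weight=float(d.get("r", d.get("weight", 0.0))),
            qvalue=float(d.get("q", d.get("qvalue", 1.0))),
            depth=int(d.get("depth", 1)),
        )
    nx.write_gml(out, str(path))


def read_gml(path: str | Path) -> nx.Graph:
    """Parse a GML file back to a graph keyed by node label."""
    g = nx.read_gml(str(path), label="label")
    return g


# ---------------------------------------------------------------------------
# JSON manifest
# ---------------------------------------------------------------------------

def write_manifest(run: RunManifest, path: str | Path) -> None:
    doc = dataclasses.asdict(run)
    try:
        text = json.dumps(doc, indent=2, sort_keys=True, allow_nan=False)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"manifest is not JSON-serializable: {exc}") from exc
    with open(path, "w") as fh:
        fh.write(text + "\n")


def read_manifest(path: str | Path) -> RunManifest:
    with open(path) as fh:
        doc = json.load(fh)
    return RunManifest(**doc)
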