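"""Reading and writing the package's plain-text formats.

Time series, connectivity matrices and incidence matrices travel as TSV
(tab-separated, '.' decimal); comma- or whitespace-separated input is
sniffed automatically.  Matrices are written with 17 significant digits so
a write/read round trip is exact.  Every matrix output carries a sidecar
``<file>.meta`` record of ``key: value`` lines (kind, subject id,
threshold, package version).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fcn import ConnectivityMatrix, HypergraphIncidence, RoiTimeSeries

_MATRIX_FMT = "%.17g"

_LABEL_CODES = {"1": 1, "0": 0, "asd": 1, "nc": 0, "+1": 1, "-1": 0}


def _sniff_delimiter(line: str) -> str | None:
    if "\t" in line:
        return "\t"
    if "," in line:
        return ","
    return None  # any whitespace


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_time_series(
    path: str | Path, subject_id: str | None = None, label: int | None = None
) -> RoiTimeSeries:
    """Load one subject's T x N matrix (rows = timepoints, columns = ROIs).

    An optional single header row supplies ROI labels; otherwise labels
    default to "ROI_001"...  Malformed input is rejected with the offending
    line (and column) named.
    """
    path = Path(path)
    raw = [ln for ln in path.read_text().splitlines()]
    lines = [(i + 1, ln) for i, ln in enumerate(raw) if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: file is empty")
    delim = _sniff_delimiter(lines[0][1])
    split = (lambda s: s.split(delim)) if delim else (lambda s: s.split())

    first_tokens = [t.strip() for t in split(lines[0][1])]
    has_header = not all(_is_number(t) for t in first_tokens)
    roi_labels = [t for t in first_tokens] if has_header else None
    body = lines[1:] if has_header else lines
    if not body:
        raise ValueError(f"{path}: no data rows")

    n_cols = len(first_tokens)
    rows = []
    for lineno, ln in body:
        tokens = [t.strip() for t in split(ln)]
        if len(tokens) != n_cols:
            raise ValueError(
                f"{path}: line {lineno}: expected {n_cols} fields, got {len(tokens)}"
            )
        values = []
        for c, tok in enumerate(tokens):
            if not _is_number(tok):
                raise ValueError(
                    f"{path}: line {lineno}, column {c + 1}: "
                    f"non-numeric value {tok!r}"
                )
            values.append(float(tok))
        rows.append(values)
    data = np.asarray(rows, dtype=float)
    if data.shape[0] < 4 or data.shape[1] < 4:
        raise ValueError(
            f"{path}: need at least 4 timepoint rows and 4 ROI columns, "
            f"got {data.shape[0]} x {data.shape[1]}"
        )
    if roi_labels is None:
        roi_labels = [f"ROI_{i + 1:03d}" for i in range(data.shape[1])]
    return RoiTimeSeries(
        data=data,
        roi_labels=roi_labels,
        subject_id=subject_id or path.stem,
        label=label,
    )


def write_time_series(ts: RoiTimeSeries, path: str | Path) -> None:
    path = Path(path)
    labels = ts.roi_labels or [f"ROI_{i + 1:03d}" for i in range(ts.n_rois)]
    with path.open("w") as fh:
        fh.write("\t".join(labels) + "\n")
        np.savetxt(fh, ts.data, delimiter="\t", fmt=_MATRIX_FMT)


def write_sidecar(path: str | Path, meta: dict) -> None:
    """Plain-text ``key: value`` metadata next to a matrix file."""
    lines = [f"{k}: {meta[k]}" for k in meta]
    Path(str(path) + ".meta").write_text("\n".join(lines) + "\n")


def read_sidecar(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for ln in Path(str(path) + ".meta").read_text().splitlines():
        if ln.strip():
            k, _, v = ln.partition(":")
            out[k.strip()] = v.strip()
    return out


def write_connectivity_matrix(cm: ConnectivityMatrix, path: str | Path) -> None:
    from . import __version__

    path = Path(path)
    np.savetxt(path, cm.values, delimiter="\t", fmt=_MATRIX_FMT)
    write_sidecar(
        path,
        {
            "kind": cm.kind,
            "subject_id": cm.subject_id,
            "n_rois": cm.n,
            "degenerate_pairs": sorted(cm.degenerate_pairs),
            "hyperfcn_version": __version__,
        },
    )


def read_matrix(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, delimiter="\t", ndmin=2)


def write_incidence(hg: HypergraphIncidence, path: str | Path, subject_id: str = "") -> None:
    from . import __version__

    path = Path(path)
    np.savetxt(path, hg.H, delimiter="\t", fmt="%d")
    write_sidecar(
        path,
        {
            "kind": "hypergraph_incidence",
            "subject_id": subject_id,
            "threshold": hg.threshold,
            "hyperfcn_version": __version__,
        },
    )


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Cohort manifest: columns subject_id, path, label (ASD/NC or 1/0).

    Relative subject paths are resolved against the manifest's directory.
    """
    path = Path(path)
    sep = _sniff_delimiter(path.read_text().splitlines()[0]) or r"\s+"
    df = pd.read_csv(path, sep=sep, dtype=str, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = {"subject_id", "path", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    labels = []
    for i, raw in enumerate(df["label"]):
        code = _LABEL_CODES.get(str(raw).strip().lower())
        if code is None:
            raise ValueError(
                f"{path}: row {i + 2}: label {raw!r} not one of ASD/NC/1/0"
            )
        labels.append(code)
    df["label"] = labels
    df["path"] = [
        str((path.parent / p) if not Path(p).is_absolute() else Path(p))
        for p in df["path"]
    ]
    return df[["subject_id", "path", "label"]]


def load_cohort(manifest_path: str | Path) -> list[RoiTimeSeries]:
    df = read_manifest(manifest_path)
    return [
        read_time_series(row.path, subject_id=row.subject_id, label=int(row.label))
        for row in df.itertuples(index=False)
    ]


def write_cohort(
    cohort: list[RoiTimeSeries], outdir: str | Path, ground_truth=None
) -> Path:
    """Write per-subject TSVs plus a manifest (and optional ground truth JSON)."""
    outdir = Path(outdir)
    (outdir / "subjects").mkdir(parents=True, exist_ok=True)
    records = []
    for ts in cohort:
        rel = f"subjects/{ts.subject_id}.tsv"
        write_time_series(ts, outdir / rel)
        records.append(
            {
                "subject_id": ts.subject_id,
                "path": rel,
                "label": "ASD" if ts.label == 1 else "NC",
            }
        )
    manifest = outdir / "manifest.tsv"
    pd.DataFrame(records).to_csv(manifest, sep="\t", index=False)
    if ground_truth is not None:
        (outdir / "ground_truth.json").write_text(
            json.dumps(ground_truth.to_dict(), indent=2) + "\n"
        )
    return manifest


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=False) + "\n")
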