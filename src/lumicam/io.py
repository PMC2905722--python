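"""Writers and readers for exit tables, flux images and run metadata.

Exit records go to a TSV table (columns x, y, z, dx, dy, dz, weight; all
lengths mm) with ``# key: value`` header comments; full float precision
(%.17g) keeps round trips and repeated runs byte-identical.  Flux images
are written both as 32-bit float TIFF and as a plain whitespace-delimited
matrix, with a JSON metadata sidecar recording lens, detector, seed and
photon count.  The exit-table header notes the termination flag
convention (photon_dead: 1 = absorbed in tissue, 0 = transmitted); only
transmitted packages appear in the table.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .optics import FluxImage
from .tissue import ExitRecords

_EXIT_COLUMNS = "x\ty\tz\tdx\tdy\tdz\tweight"


def save_exits_tsv(path, exits: ExitRecords, metadata: dict | None = None) -> None:
    path = Path(path)
    lines = []
    meta = dict(metadata or {})
    meta.setdefault("photon_dead_convention", "1=absorbed,0=transmitted")
    for key in sorted(meta):
        lines.append(f"# {key}: {meta[key]}")
    lines.append("# " + _EXIT_COLUMNS)
    table = np.column_stack(
        [exits.positions, exits.directions, exits.weights[:, None]]
    )
    body = "\n".join(
        "\t".join(f"{v:.17g}" for v in row) for row in table
    )
    text = "\n".join(lines)
    if body:
        text += "\n" + body
    path.write_text(text + "\n")


def load_exits_tsv(path) -> ExitRecords:
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append([float(tok) for tok in line.split("\t")])
    if not rows:
        return ExitRecords.empty()
    arr = np.asarray(rows, dtype=float)
    return ExitRecords(arr[:, 0:3], arr[:, 3:6], arr[:, 6])


def save_flux_image(base_path, image: FluxImage) -> dict[str, Path]:
    """Write <base>.tif, <base>.txt and <base>.json; returns the paths."""
    base = Path(base_path)
    base.parent.mkdir(parents=True, exist_ok=True)
    tif = base.with_suffix(".tif")
    txt = base.with_suffix(".txt")
    meta_path = base.with_suffix(".json")
    tifffile.imwrite(tif, image.oriented().astype(np.float32))
    np.savetxt(txt, image.data, fmt="%.9g")
    meta_path.write_text(json.dumps(_jsonable(image.metadata), indent=2, sort_keys=True))
    return {"tiff": tif, "text": txt, "metadata": meta_path}


def save_run_summary(path, summary: dict) -> None:
    Path(path).write_text(json.dumps(_jsonable(summary), indent=2, sort_keys=True))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
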