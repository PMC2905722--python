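"""End-to-end simulation: tissue stage, free-space stage, output writing."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from . import __version__
from .config import RunConfig, camera_for, config_hash
from .io import save_exits_tsv, save_flux_image, save_run_summary
from .optics import FluxImage, accumulate
from .parallel import MergedResult, run_parallel
from .tissue import ExitRecords


@dataclass
class SimulationResult:
    """Merged tissue output plus the rendered CCD flux image."""

    merged: MergedResult
    image: FluxImage
    config: RunConfig
    perspective: str


def render(
    exits: ExitRecords,
    config: RunConfig,
    perspective: Optional[str] = None,
    extra_metadata: Optional[dict] = None,
) -> FluxImage:
    """Free-space stage: map exit records through the camera onto the CCD."""
    name = perspective or config.perspective
    lens, det = camera_for(config, name)
    meta = {
        "perspective": name,
        "seed": config.seed,
        "photons": config.photons,
        "config_hash": config_hash(config),
        "version": __version__,
    }
    if extra_metadata:
        meta.update(extra_metadata)
    return accumulate(exits, lens, det, config.tau.build(), metadata=meta)


def simulate(
    config: RunConfig,
    n_workers: Optional[int] = None,
    perspective: Optional[str] = None,
) -> SimulationResult:
    """Full pipeline: parallel tissue transport, then the camera stage."""
    merged = run_parallel(config, n_workers)
    image = render(merged.exits, config, perspective)
    return SimulationResult(
        merged=merged,
        image=image,
        config=config,
        perspective=perspective or config.perspective,
    )


def write_outputs(result: SimulationResult, out_dir) -> dict:
    """Write exit TSV, flux image (TIFF + text + metadata) and run summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    meta = {
        "seed": cfg.seed,
        "photons": cfg.photons,
        "perspective": result.perspective,
        "config_hash": result.merged.config_hash,
        "generator": f"mcg(a={cfg.rng.multiplier}, m={cfg.rng.modulus})",
        "version": __version__,
    }
    save_exits_tsv(out / "exits.tsv", result.merged.exits, meta)
    paths = save_flux_image(out / f"flux_{result.perspective}", result.image)
    ledger = result.merged.ledger
    summary = dict(meta)
    summary.update(
        {
            "ledger": {
                "launched": ledger.launched,
                "absorbed": ledger.absorbed,
                "exited": ledger.exited,
                "roulette_net": ledger.roulette_net,
                "closure_residual": ledger.closure_residual,
            },
            "exit_count": len(result.merged.exits),
            "accepted": result.image.metadata.get("accepted"),
            "image_total": result.image.total(),
            "workers": result.merged.diagnostics,
        }
    )
    save_run_summary(out / "summary.json", summary)
    paths["exits"] = out / "exits.tsv"
    paths["summary"] = out / "summary.json"
    return paths
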