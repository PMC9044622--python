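"""End-to-end orchestration: one call per image, plus batch processing.

``process_image`` runs nucleus segmentation, then whole-cell segmentation
in one of three modes — ``average`` (the multi-threshold reconstruction,
for cells well separated from red blood cells), ``watershed`` or ``slic``
(the touching-cell fallbacks) — and derives the cytoplasm.  Everything it
decided (thresholds, branch, seed) is collected in an audit record.

``run_pipeline`` maps that over a list of files, writing mask PNGs and
audit JSON per image and a batch summary table at the end.  All modes are
deterministic for a fixed configuration.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import imgio, metrics, touching, wbc
from .errors import LminsegError
from .nucleus import NucleusParams, segment_nucleus

__all__ = ["PipelineConfig", "process_image", "run_pipeline"]

logger = logging.getLogger("lminseg")

#: a WBC mask covering more than this fraction of the image, or touching
#: the border, suggests the averaging strategy merged touching cells
_AREA_SANITY_FRAC = 0.5


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline parameters with their defaults."""

    er: float = 0.07
    n1: int = 3
    n2: int = 3
    nbins: int = 256
    n_thresholds: int = 10
    min_area_frac: float = 0.005
    mode: str = "average"          # average | watershed | slic
    slic_segments: int = 100
    slic_compactness: float | None = None   # None: 10 for color, 1 for gray
    watershed_min_distance: int | None = None
    seed: int = 0

    def nucleus_params(self) -> NucleusParams:
        return NucleusParams(
            er=self.er, n1=self.n1, n2=self.n2, nbins=self.nbins,
            min_area_frac=self.min_area_frac,
        )


def process_image(
    gray: np.ndarray,
    config: PipelineConfig | None = None,
    color: np.ndarray | None = None,
) -> dict:
    """Segment nucleus, WBC and cytoplasm of one gray image.

    Returns a dict with boolean masks ``nucleus``, ``wbc``, ``cytoplasm``
    and an ``audit`` sub-dict (initial value, extrema, branch, thresholds).
    ``color`` is only consulted in ``slic`` mode.
    """
    cfg = config or PipelineConfig()
    nmask, estimate = segment_nucleus(gray, cfg.nucleus_params())
    audit = estimate.to_dict()
    audit["mode"] = cfg.mode

    if cfg.mode == "average":
        wmask, cyto, t_otsu = wbc.segment_wbc(
            gray, nmask, cfg.n_thresholds, cfg.nucleus_params()
        )
        audit["otsu_t"] = t_otsu
        border = (
            wmask[0].any() or wmask[-1].any()
            or wmask[:, 0].any() or wmask[:, -1].any()
        )
        if border or wmask.sum() > _AREA_SANITY_FRAC * wmask.size:
            warnings.warn(
                "WBC mask touches the image border or is implausibly large; "
                "the cell may touch red blood cells — consider "
                "mode='slic' or mode='watershed'",
                stacklevel=2,
            )
    elif cfg.mode == "watershed":
        wmask = touching.segment_wbc_watershed(
            gray, nmask, cfg.min_area_frac, cfg.watershed_min_distance
        )
        cyto = wbc.compute_cytoplasm(wmask, nmask)
        audit["otsu_t"] = None
    elif cfg.mode == "slic":
        src = color if color is not None else gray
        wmask = touching.segment_wbc_slic(
            src, nmask, cfg.slic_segments, cfg.slic_compactness,
            cfg.min_area_frac,
        )
        cyto = wbc.compute_cytoplasm(wmask, nmask)
        audit["otsu_t"] = None
    else:
        raise LminsegError(f"unknown mode {cfg.mode!r}")

    return {"nucleus": nmask, "wbc": wmask, "cytoplasm": cyto, "audit": audit}


def run_pipeline(
    config: PipelineConfig, inputs: list, outdir, summary_name: str = "summary"
) -> int:
    """Process a list of image files; write masks, per-image audit JSON and
    a batch summary CSV under ``outdir``.

    Per-image failures are logged and skipped; the exit status is non-zero
    only when every image fails.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = []
    failures = 0
    for path in inputs:
        path = Path(path)
        stem = path.stem
        try:
            gray = imgio.read_image(path)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                result = process_image(gray, config)
            imgio.write_mask(result["nucleus"], outdir / f"{stem}_nucleus.png")
            imgio.write_mask(result["wbc"], outdir / f"{stem}_wbc.png")
            imgio.write_mask(result["cytoplasm"], outdir / f"{stem}_cytoplasm.png")
            audit = dict(result["audit"])
            (outdir / f"{stem}_audit.json").write_text(
                json.dumps(audit, indent=2) + "\n"
            )
            record = {
                "image": stem,
                "epsilon_t": audit["epsilon_t"],
                "T_nc0": audit["T_nc0"],
                "branch": audit["branch"],
                "otsu_t": audit.get("otsu_t"),
                "nucleus_pred_size": int(result["nucleus"].sum()),
                "wbc_pred_size": int(result["wbc"].sum()),
            }
            if result["nucleus"].any() and result["cytoplasm"].any():
                record["contrast"] = metrics.region_contrast(
                    gray, result["nucleus"], result["cytoplasm"]
                )
            records.append(record)
            logger.info(
                "%s: eps_t=%.4f branch=%s nucleus=%dpx wbc=%dpx",
                stem, audit["epsilon_t"], audit["branch"],
                record["nucleus_pred_size"], record["wbc_pred_size"],
            )
        except (LminsegError, OSError) as exc:
            failures += 1
            logger.warning("%s: skipped (%s)", path, exc)
    if records:
        pd.DataFrame.from_records(records).to_csv(
            outdir / f"{summary_name}.csv", index=False
        )
    return 1 if failures and not records else 0
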