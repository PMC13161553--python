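"""In vitro digestible energy (IVDE) from digestion-tube records.

Each tube charges ``w_t`` kg DM of sample with gross energy ``ge_t``
(kcal); after simulated gastric/small-intestinal/large-intestinal
digestion the defatted dried residue retains ``ge_r`` kcal.  An enzyme
blank (digestive fluids only) leaves ``ge_e`` kcal of residue, which is
added back so that enzyme-derived residue does not count as undigested
sample energy:

    IVDE = ((ge_t - ge_r) + ge_e) / w_t        [kcal/kg DM]
"""

from __future__ import annotations

import logging
import warnings
from statistics import mean, stdev
from typing import Iterable, Optional

from .types import InVitroRun, InvalidRecordError

logger = logging.getLogger(__name__)

#: replicate CV (%) above which an in vitro run set is flagged
CV_ANOMALY_THRESHOLD = 5.0


def compute_ivde(run: InVitroRun) -> float:
    """Blank-corrected IVDE (kcal/kg DM) of one digestion tube."""
    if run.ge_r > run.ge_t + run.ge_e:
        warnings.warn(
            f"{run.sample_id}: residue energy {run.ge_r} exceeds sample + blank "
            f"energy ({run.ge_t + run.ge_e}); negative digestibility"
        )
    return ((run.ge_t - run.ge_r) + run.ge_e) / run.w_t


def mean_batch_blank(runs: Iterable[InVitroRun]) -> dict[int, float]:
    """Mean enzyme-blank residue energy (kcal) per digestion batch."""
    by_batch: dict[int, list[float]] = {}
    for r in runs:
        by_batch.setdefault(r.batch, []).append(r.ge_e)
    return {b: mean(v) for b, v in by_batch.items()}


def apply_batch_blank(run: InVitroRun, blanks: dict[int, float]) -> InVitroRun:
    """Replace a tube's blank energy with its batch-mean blank."""
    if run.batch not in blanks:
        raise KeyError(f"no blank recorded for batch {run.batch}")
    return InVitroRun(
        sample_id=run.sample_id,
        w_t=run.w_t,
        ge_t=run.ge_t,
        ge_r=run.ge_r,
        ge_e=blanks[run.batch],
        batch=run.batch,
    )


def ivde_summary(
    runs: Iterable[InVitroRun],
    sample_id: str,
) -> tuple[float, Optional[float]]:
    """Replicate mean and CV (%) of IVDE for one sample.

    With a single replicate the CV is undefined (returned as ``None``,
    logged).  Replicate CVs above ``CV_ANOMALY_THRESHOLD`` are logged as
    protocol anomalies — the in vitro assay is expected to be far more
    repeatable than the in vivo bioassay.
    """
    vals = [compute_ivde(r) for r in runs if r.sample_id == sample_id]
    if not vals:
        raise KeyError(f"no in vitro runs for sample {sample_id}")
    m = mean(vals)
    if len(vals) < 2:
        logger.warning("sample %s: single replicate, CV undefined", sample_id)
        return m, None
    cv = 100.0 * stdev(vals) / m
    if cv > CV_ANOMALY_THRESHOLD:
        logger.warning(
            "sample %s: replicate CV %.2f%% exceeds %.1f%% (protocol anomaly?)",
            sample_id, cv, CV_ANOMALY_THRESHOLD,
        )
    return m, cv


def tube_from_concentration(
    sample_id: str,
    w_t: float,
    ge_concentration: float,
    ge_r: float,
    ge_e: float,
    batch: int = 1,
) -> InVitroRun:
    """Build a tube record when only the sample's GE concentration is known.

    Tube-level sample energy is derived as ``ge_t = w_t * GE`` (kcal)
    from the ingredient's GE concentration (kcal/kg DM); tube-level GE is
    rarely measured separately.
    """
    if ge_concentration <= 0:
        raise InvalidRecordError(f"{sample_id}: GE concentration must be > 0")
    return InVitroRun(
        sample_id=sample_id,
        w_t=w_t,
        ge_t=w_t * ge_concentration,
        ge_r=ge_r,
        ge_e=ge_e,
        batch=batch,
    )
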