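"""Per-crop feature assembly into one labeled observation table.

Each observation is one physical crop with both detection channels present:
five co-occurrence texture features and the packing coefficient per channel,
three spectral features per channel, and the three fiber morphometrics from
the forward channel only — 21 features in all.  Records with any missing
value (e.g. undefined correlation on a flat crop, or no traceable fibers)
are flagged and excluded from model fitting.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .fibers import enhance, extract_fibers, fiber_metrics, packing_coefficient
from .io import Channel, SHGField
from .spectral import spectral_features
from .texture import glcm, haralick_features, quantize

logger = logging.getLogger(__name__)

__all__ = ["FEATURE_NAMES", "featurize_crop", "build_table", "class_summary"]

_PER_CHANNEL = ("asm", "entropy", "idm", "contrast", "correlation",
                "alignment", "amplitude", "time_constant", "packing")
_FORWARD_ONLY = ("fiber_length", "fiber_width", "fiber_straightness")

#: the 21 per-crop feature names ([F]/[B] = forward/backward channel)
FEATURE_NAMES: Tuple[str, ...] = tuple(
    f"{name}_{ch}" for name in _PER_CHANNEL for ch in ("F", "B")
) + _FORWARD_ONLY


def featurize_crop(
    fwd: np.ndarray,
    bwd: np.ndarray,
    pixel_size_um: float,
    glcm_levels: int = 64,
    min_fiber_length_px: float = 20.0,
) -> Dict[str, float]:
    """Compute the 21 named features of one paired-channel crop."""
    out: Dict[str, float] = {}
    for ch, img in (("F", np.asarray(fwd)), ("B", np.asarray(bwd))):
        tex = haralick_features(glcm(quantize(img, glcm_levels), levels=glcm_levels))
        for k, v in tex.as_dict().items():
            out[f"{k}_{ch}"] = v
        spec = spectral_features(img, pixel_size_um=pixel_size_um)
        for k, v in spec.as_dict().items():
            out[f"{k}_{ch}"] = v
        out[f"packing_{ch}"] = packing_coefficient(img)
    fibers = extract_fibers(enhance(np.asarray(fwd, dtype=float)),
                            min_fiber_length_px=min_fiber_length_px)
    for k, v in fiber_metrics(fibers, pixel_size_um).as_dict().items():
        out[k] = v
    return out


def build_table(
    crops: Iterable[Tuple[str, SHGField, SHGField]],
    glcm_levels: int = 64,
    min_fiber_length_px: float = 20.0,
) -> pd.DataFrame:
    """Assemble one labeled record per paired-channel crop.

    ``crops`` yields ``(label, forward_field, backward_field)``; the two
    fields must describe the same physical crop.  The returned DataFrame has
    columns ``crop_id``, ``label``, the 21 features, and ``complete`` (False
    when any feature is missing — such records are excluded from model
    fitting downstream).
    """
    records: List[dict] = []
    for i, (label, fwd, bwd) in enumerate(crops):
        if fwd.channel != Channel.FORWARD or bwd.channel != Channel.BACKWARD:
            warnings.warn(f"crop {i}: channel mismatch, record skipped", stacklevel=2)
            continue
        if fwd.pixels.shape != bwd.pixels.shape:
            warnings.warn(f"crop {i}: channel shapes differ, record skipped", stacklevel=2)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # per-crop degeneracies are flagged via NaN
            feats = featurize_crop(fwd.pixels, bwd.pixels, fwd.pixel_size_um,
                                   glcm_levels, min_fiber_length_px)
        rec = {"crop_id": fwd.stack_id or f"crop_{i:04d}", "label": label}
        rec.update(feats)
        rec["complete"] = bool(np.all(np.isfinite([feats[k] for k in FEATURE_NAMES])))
        records.append(rec)
    df = pd.DataFrame.from_records(records)
    if len(df):
        n_bad = int((~df["complete"]).sum())
        if n_bad:
            logger.warning("%d of %d records have missing features and will be "
                           "excluded from model fitting", n_bad, len(df))
    return df


def class_summary(
    table: pd.DataFrame,
    feature: str,
    groups: Optional[Sequence[str]] = None,
    holm: bool = False,
) -> pd.DataFrame:
    """Per-group mean/SD of one feature plus pairwise rank-sum p-values.

    Uses the two-sided Wilcoxon rank-sum test, robust to the skewed fiber
    metrics.  Per-comparison p-values by default; ``holm=True`` applies a
    Holm step-down correction across the pairs.
    """
    if feature not in table.columns:
        raise KeyError(f"unknown feature {feature!r}")
    if groups is None:
        groups = sorted(table["label"].unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    vals = {g: table.loc[table["label"] == g, feature].dropna().to_numpy() for g in groups}

    rows = []
    for g in groups:
        rows.append({"group": g, "n": len(vals[g]),
                     "mean": float(np.mean(vals[g])) if len(vals[g]) else np.nan,
                     "sd": float(np.std(vals[g], ddof=1)) if len(vals[g]) > 1 else np.nan})
    pairs, pvals = [], []
    for a, b in itertools.combinations(groups, 2):
        if len(vals[a]) < 3 or len(vals[b]) < 3:
            warnings.warn(f"pair ({a}, {b}) skipped: fewer than 3 records in a group",
                          stacklevel=2)
            continue
        p = float(stats.ranksums(vals[a], vals[b]).pvalue)
        pairs.append((a, b))
        pvals.append(p)
    if holm and pvals:
        order = np.argsort(pvals)
        m = len(pvals)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * pvals[idx])
            adj[idx] = min(1.0, running)
        pvals = list(adj)

    summary = pd.DataFrame(rows)
    tests = pd.DataFrame(
        [{"group_a": a, "group_b": b, "p_value": p} for (a, b), p in zip(pairs, pvals)]
    )
    summary.attrs["pairwise"] = tests
    return summary
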