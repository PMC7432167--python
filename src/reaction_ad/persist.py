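"""Serialization of fitted AD pipelines to a single archive."""

from __future__ import annotations

from pathlib import Path

import joblib

FORMAT_VERSION = 1

__all__ = ["save_pipeline", "load_pipeline", "FORMAT_VERSION"]


def save_pipeline(path: str | Path, featurizer, ad_model, forest=None,
                  metadata: dict | None = None) -> None:
    """Archive a fitted featurizer + AD model (+ optional QRPR forest)."""
    payload = {
        "format_version": FORMAT_VERSION,
        "featurizer": featurizer,
        "ad_model": ad_model,
        "forest": forest,
        "metadata": metadata or {},
    }
    joblib.dump(payload, path)


def load_pipeline(path: str | Path) -> dict:
    payload = joblib.load(path)
    version = payload.get("format_version")
    if version != FORMAT_VERSION:
        raise ValueError(f"unsupported model archive version {version!r}")
    return payload
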