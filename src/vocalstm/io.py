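"""WAV and CSV I/O for corpora (PCM 16-bit mono, metadata sidecar)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .exceptions import DataError
from .synth import Vocalization

__all__ = ["write_corpus", "read_corpus", "read_wav"]

_META_COLS = [
    "speaker_id",
    "category",
    "fieldsite",
    "country",
    "language_family",
    "subregion",
    "region",
    "duration_s",
    "path",
]


def write_corpus(corpus: list[Vocalization], out_dir: str | Path) -> Path:
    """Write one 16-bit PCM WAV per vocalization plus a metadata CSV; returns
    the metadata path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for v in corpus:
        name = f"{v.speaker_id}_{v.category}.wav"
        peak = np.abs(v.samples).max()
        x = v.samples / peak * 0.95 if peak > 0 else v.samples
        wavfile.write(out_dir / name, int(v.rate), (x * 32767).astype(np.int16))
        row = v.meta()
        row["path"] = name
        rows.append(row)
    meta_path = out_dir / "metadata.csv"
    pd.DataFrame(rows)[_META_COLS].to_csv(meta_path, index=False)
    return meta_path


def read_wav(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a WAV file to float64 in [-1, 1]; stereo inputs are reduced to
    the channel with higher RMS (the louder channel carries the speaker in
    dual-microphone field recordings)."""
    rate, data = wavfile.read(path)
    if data.size == 0:
        raise DataError(f"empty WAV file: {path}")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / np.iinfo(data.dtype).max
    else:
        data = data.astype(np.float64)
    if data.ndim == 2:
        rms = np.sqrt((data**2).mean(axis=0))
        data = data[:, int(np.argmax(rms))]
    return data, float(rate)


def read_corpus(meta_path: str | Path) -> list[Vocalization]:
    """Load a corpus from a metadata CSV produced by :func:`write_corpus`
    (WAV paths are resolved relative to the CSV)."""
    meta_path = Path(meta_path)
    meta = pd.read_csv(meta_path)
    corpus = []
    for _, row in meta.iterrows():
        samples, rate = read_wav(meta_path.parent / row["path"])
        corpus.append(
            Vocalization(
                samples=samples,
                rate=rate,
                speaker_id=str(row["speaker_id"]),
                category=str(row["category"]),
                fieldsite=str(row.get("fieldsite", "")),
                country=str(row.get("country", "")),
                language_family=str(row.get("language_family", "")),
                subregion=str(row.get("subregion", "")),
                region=str(row.get("region", "")),
            )
        )
    return corpus
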