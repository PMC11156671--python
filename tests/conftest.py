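"""Shared fixtures and independent oracles for the vocalstm test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

import vocalstm as v
from vocalstm.modspec import STMDataset


# ---------------------------------------------------------------------------
# independent oracles (never share code with the implementation paths they
# check)


def autocorr_dft_power(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Brute-force modulation power: explicit 2D linear autocorrelation of the
    mean-removed array followed by a 2D DFT (Wiener-Khinchin route).

    Returns (oracle_power, direct_power) on the (2*nt-1, 2*nf-1) padded grid
    with the same normalization as :func:`vocalstm.modulation_power`.
    """
    from scipy.signal import correlate2d

    x = np.asarray(values, dtype=float)
    nt, nf = x.shape
    xm = x - x.mean()
    acf = correlate2d(xm, xm, mode="full")  # (2nt-1, 2nf-1)
    s = (2 * nt - 1, 2 * nf - 1)
    # DFT magnitude of the acf equals |DFT(x_padded)|^2 (shift only adds phase)
    oracle = np.abs(np.fft.fft2(acf, s=s)) / (s[0] * s[1] * nt * nf)
    direct = np.abs(np.fft.fft2(xm, s=s)) ** 2 / (s[0] * s[1] * nt * nf)
    return oracle, direct


def exact_signflip_pvalues(diffs: np.ndarray) -> np.ndarray:
    """Two-tailed p-values of the paired t statistic under exhaustive
    enumeration of all 2^n within-pair sign assignments."""
    D = np.asarray(diffs, dtype=float)
    n = D.shape[0]
    t_all = []
    for signs in itertools.product((-1.0, 1.0), repeat=n):
        S = np.asarray(signs)[:, None] * D
        m = S.mean(axis=0)
        sd = S.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_all.append(m / (sd / np.sqrt(n)))
    t_all = np.asarray(t_all)  # (2^n, cells)
    t_obs = t_all[-1]  # all +1 signs = observed
    return (np.abs(t_all) >= np.abs(t_obs)[None, :]).mean(axis=0)


def nipals_pls1(X: np.ndarray, y: np.ndarray, n_components: int) -> np.ndarray:
    """Reference PLS1 fit via textbook NIPALS on standardized data; returns
    fitted responses in original y units."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    x_mean, x_std = X.mean(axis=0), X.std(axis=0, ddof=1)
    x_std[x_std == 0] = 1.0
    y_mean, y_std = y.mean(), y.std(ddof=1)
    E = (X - x_mean) / x_std
    f = (y - y_mean) / y_std
    fitted = np.zeros_like(f)
    for _ in range(n_components):
        w = E.T @ f
        w = w / np.linalg.norm(w)
        t = E @ w
        tt = t @ t
        p = E.T @ t / tt
        q = (f @ t) / tt
        fitted = fitted + q * t
        E = E - np.outer(t, p)
        f = f - q * t
    return fitted * y_std + y_mean


def make_stm_dataset(
    X: np.ndarray,
    spectral_axis: np.ndarray,
    temporal_axis: np.ndarray,
    n_groups: int = 2,
) -> STMDataset:
    """Wrap a raw samples x cells matrix (rows alternating song/speech per
    speaker) into an STMDataset with minimal paired metadata."""
    n = X.shape[0]
    assert n % 2 == 0
    rows = []
    for i in range(n // 2):
        g = i % n_groups
        for cat in ("song", "speech"):
            rows.append(
                {
                    "speaker_id": f"s{i:03d}",
                    "category": cat,
                    "fieldsite": f"site{g:02d}",
                    "country": f"country{g:02d}",
                    "language_family": f"family{g:02d}",
                    "subregion": f"subregion{g:02d}",
                    "region": f"region{g:02d}",
                    "duration_s": 3.0,
                }
            )
    return STMDataset(
        X=np.asarray(X, dtype=float),
        spectral_axis=np.asarray(spectral_axis, dtype=float),
        temporal_axis=np.asarray(temporal_axis, dtype=float),
        meta=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def grid() -> v.StmGrid:
    return v.analysis_grid()


@pytest.fixture(scope="session")
def small_corpus() -> tuple[v.CorpusSpec, list]:
    spec = v.CorpusSpec(n_groups=6, speakers_per_group=5, duration_s=(2.5, 3.5), seed=11)
    return spec, v.synth_corpus(spec)


@pytest.fixture(scope="session")
def small_stm(small_corpus, grid) -> v.STMDataset:
    _, corpus = small_corpus
    return v.batch_stm(corpus, grid)


@pytest.fixture(scope="session")
def study(grid):
    """The full desk-scale study: 21 societies x 15 paired speakers at the
    default (frozen) corpus conditions, with contrast map and decoding.
    Shared across the acceptance-level tests."""
    spec = v.CorpusSpec(seed=1)
    corpus = v.synth_corpus(spec)
    stm = v.batch_stm(corpus, grid)
    statmap = v.paired_permutation_map(stm, n_perm=10000, alpha=0.001, seed=101)
    decode = v.decode_stm(stm, grouping="fieldsite", lam=0.01)
    return {"spec": spec, "corpus": corpus, "stm": stm, "statmap": statmap, "decode": decode}
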