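"""End-to-end orchestration: synth -> stm -> contrast -> decode -> behavior -> pls.

Every stage seeds its randomness from ``RunConfig.seed`` plus a fixed
per-stage offset, so a rerun with the same configuration reproduces every
array bit-identically. Results can be persisted to an HDF5 container with
CSV mirrors for tabular outputs and a JSON provenance record.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .acoustic import PLSMap, important_features, pls_correlation_map
from .contrast import StatMap, find_peaks, kmeans_stat_peaks, paired_permutation_map, society_overlap_map
from .decode import (
    DecodeResult,
    FeatureSetComparison,
    WilcoxonResult,
    compare_feature_sets,
    correlate_accuracy_with_covariate,
    decode_stm,
    roc_per_group,
    wilcoxon_vs_chance,
)
from .exceptions import DependencyError, ParameterError
from .modspec import STMDataset, StmGrid, analysis_grid, batch_stm
from .perception import (
    CorrMap,
    attach_metadata,
    decoding_behavior_corr,
    mean_ratings,
    speaker_behavior_diffs,
    stm_behavior_corr_map,
    stm_diff_matrix,
)
from .synth import CorpusSpec, Vocalization, synth_acoustic_table, synth_corpus, synth_ratings

__all__ = ["RunConfig", "PipelineResults", "ResultsContainer", "run_pipeline", "summarize"]

log = logging.getLogger(__name__)

STAGES = ("synth", "stm", "contrast", "decode", "behavior", "pls")
# upstream products (state keys) each stage requires
_DEPS = {
    "synth": (),
    "stm": ("corpus",),
    "contrast": ("stm",),
    "decode": ("stm",),
    "behavior": ("stm", "statmap", "decode"),
    "pls": ("stm", "statmap"),
}


@dataclass
class RunConfig:
    """All knobs of one pipeline run; fully dumped into provenance."""

    seed: int = 0
    corpus: CorpusSpec | None = field(default_factory=CorpusSpec)
    audio_meta: str | None = None  # metadata CSV of an on-disk corpus
    grid: StmGrid = field(default_factory=analysis_grid)
    n_perm: int = 10000
    contrast_alpha: float = 0.001
    overlap_n_perm: int = 5000
    overlap_alpha: float = 0.05
    grouping: str = "fieldsite"
    lam: float = 0.01
    n_listeners: int = 24
    rating_noise_sd: float = 0.3
    rating_gain: float = 1.2
    behavior_alpha: float = 0.05
    n_acoustic: int = 98
    acoustic_noise_sd: float = 0.5
    pls_components: int = 10
    pls_alpha: float = 0.05
    do_overlap: bool = True
    do_comparison: bool = True
    stages: tuple[str, ...] = STAGES

    def stage_seed(self, offset: int) -> int:
        return int((self.seed + offset) % (2**31 - 1))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "corpus" in raw and raw["corpus"] is not None:
            spec = {
                k: tuple(val) if isinstance(val, list) else val
                for k, val in raw["corpus"].items()
            }
            if "class_params" in spec:
                spec["class_params"] = {
                    c: tuple(p) for c, p in dict(spec["class_params"]).items()
                }
            raw["corpus"] = CorpusSpec(**spec)
        if "grid" in raw:
            raw["grid"] = StmGrid(**raw["grid"])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


@dataclass
class PipelineResults:
    config: RunConfig
    corpus: list[Vocalization] | None = None
    stm: STMDataset | None = None
    statmap: StatMap | None = None
    peaks_pos: object | None = None
    peaks_neg: object | None = None
    overlap_counts: np.ndarray | None = None
    per_group_maps: dict | None = None
    kmeans_centroids: np.ndarray | None = None
    decode: DecodeResult | None = None
    roc: dict | None = None
    wilcoxon: WilcoxonResult | None = None
    duration_corr: tuple[float, float] | None = None
    ratings: pd.DataFrame | None = None
    behavior_diffs: pd.Series | None = None
    behavior_corr_map: CorrMap | None = None
    behavior_means: pd.DataFrame | None = None
    accuracy_behavior_corr: tuple[float, float] | None = None
    acoustic_features: pd.DataFrame | None = None
    acoustic_labels: pd.DataFrame | None = None
    plsmap: PLSMap | None = None
    vip_report: pd.DataFrame | None = None
    comparison: FeatureSetComparison | None = None


def _stage_synth(cfg: RunConfig, st: dict) -> None:
    if cfg.audio_meta is not None:
        from .io import read_corpus

        st["corpus"] = read_corpus(cfg.audio_meta)
    elif cfg.corpus is not None:
        spec = dataclasses.replace(cfg.corpus, seed=cfg.stage_seed(0))
        st["corpus"] = synth_corpus(spec)
        st["corpus_spec"] = spec
    else:
        raise ParameterError("config provides neither audio inputs nor a synthetic CorpusSpec")


def _stage_stm(cfg: RunConfig, st: dict) -> None:
    st["stm"] = batch_stm(st["corpus"], cfg.grid)


def _stage_contrast(cfg: RunConfig, st: dict) -> None:
    stm = st["stm"]
    statmap = paired_permutation_map(
        stm, n_perm=cfg.n_perm, alpha=cfg.contrast_alpha, seed=cfg.stage_seed(1)
    )
    st["statmap"] = statmap
    st["peaks_pos"] = find_peaks(statmap, sign=1)
    st["peaks_neg"] = find_peaks(statmap, sign=-1)
    if cfg.do_overlap:
        # per-society tests run at a desk-scale alpha: with ~15 pairs the
        # Monte-Carlo p floor cannot clear BH at the corpus-level 0.001
        counts, _, per_group = society_overlap_map(
            stm,
            n_perm=cfg.overlap_n_perm,
            alpha=cfg.overlap_alpha,
            seed=cfg.stage_seed(2),
            by=cfg.grouping,
            corpus_map=statmap,
        )
        st["overlap_counts"] = counts
        st["per_group_maps"] = per_group
        peaksets = []
        for g, gmap in per_group.items():
            for sign in (1, -1):
                ps = find_peaks(gmap, sign=sign)
                if len(ps):
                    ps.peaks = ps.peaks.iloc[:1]  # strongest peak per sign per group
                    ps.group = g
                    peaksets.append(ps)
        if sum(len(p) for p in peaksets) >= 2:
            centroids, _, _ = kmeans_stat_peaks(peaksets, k=2, seed=cfg.stage_seed(3))
            st["kmeans_centroids"] = centroids


def _stage_decode(cfg: RunConfig, st: dict) -> None:
    stm = st["stm"]
    res = decode_stm(stm, grouping=cfg.grouping, lam=cfg.lam)
    st["decode"] = res
    st["roc"] = roc_per_group(res)
    st["wilcoxon"] = wilcoxon_vs_chance(res.fold_accuracy, seed=cfg.stage_seed(4))
    dur = stm.meta.groupby(cfg.grouping)["duration_s"].mean()
    acc = res.accuracy_by_group()
    common = acc.index.intersection(dur.index)
    if len(common) >= 4 and acc[common].std() > 0 and dur[common].std() > 0:
        st["duration_corr"] = correlate_accuracy_with_covariate(
            acc[common].to_numpy(), dur[common].to_numpy()
        )


def _stage_behavior(cfg: RunConfig, st: dict) -> None:
    stm = st["stm"]
    # listeners are driven by the significant contrast structure only
    template = (np.nan_to_num(st["statmap"].statistic) * st["statmap"].mask).ravel()
    ratings = synth_ratings(
        stm,
        template,
        noise_sd=cfg.rating_noise_sd,
        n_listeners=cfg.n_listeners,
        gain=cfg.rating_gain,
        seed=cfg.stage_seed(5),
    )
    table = attach_metadata(ratings, stm.meta)
    st["ratings"] = table
    st["behavior_means"] = mean_ratings(table, by="listener")
    diffs = speaker_behavior_diffs(table)
    st["behavior_diffs"] = diffs
    stm_diffs, speakers = stm_diff_matrix(stm)
    aligned = diffs.reindex(speakers)
    st["behavior_corr_map"] = stm_behavior_corr_map(
        stm_diffs, aligned.to_numpy(), alpha=cfg.behavior_alpha
    )
    if st.get("decode") is not None:
        acc = st["decode"].accuracy_by_group()
        spk_group = stm.meta.drop_duplicates("speaker_id").set_index("speaker_id")[cfg.grouping]
        group_beh = diffs.groupby(spk_group).mean()
        try:
            st["accuracy_behavior_corr"] = decoding_behavior_corr(acc, group_beh)
        except Exception as e:  # degenerate at tiny scale; keep the run going
            log.warning("accuracy-behaviour correlation unavailable: %s", e)


def _stage_pls(cfg: RunConfig, st: dict) -> None:
    stm = st["stm"]
    features, labels = synth_acoustic_table(
        stm, n_features=cfg.n_acoustic, noise_sd=cfg.acoustic_noise_sd, seed=cfg.stage_seed(6)
    )
    st["acoustic_features"] = features
    st["acoustic_labels"] = labels
    peaks = {}
    for name, ps in (("spectral", st["peaks_pos"]), ("temporal", st["peaks_neg"])):
        if ps is not None and len(ps):
            row = ps.peaks.iloc[0]
            peaks[name] = (row["spectral_cyc_per_khz"], row["temporal_hz"])
    plsmap = pls_correlation_map(
        features, stm, n_components=cfg.pls_components, alpha=cfg.pls_alpha, peaks=peaks
    )
    st["plsmap"] = plsmap
    if plsmap.peak_vips:
        reports = []
        for name, vip in plsmap.peak_vips.items():
            rep = important_features(vip, label_map=labels)
            rep.insert(0, "peak", name)
            reports.append(rep)
        st["vip_report"] = pd.concat(reports, ignore_index=True)
    if cfg.do_comparison:
        vip_union: list[str] = []
        for vip in plsmap.peak_vips.values():
            vip_union += list(vip[vip > 1.0].index)
        vip_union = sorted(set(vip_union))
        st["comparison"] = compare_feature_sets(
            stm, features, vip_union, grouping=cfg.grouping, lam=cfg.lam
        )


_STAGE_FN = {
    "synth": _stage_synth,
    "stm": _stage_stm,
    "contrast": _stage_contrast,
    "decode": _stage_decode,
    "behavior": _stage_behavior,
    "pls": _stage_pls,
}


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> PipelineResults:
    """Execute the configured stages in dependency order.

    Raises :class:`DependencyError` naming the first stage whose upstream
    product is missing. With ``out_dir`` set, persists an HDF5/CSV results
    container with full provenance.
    """
    unknown = set(config.stages) - set(STAGES)
    if unknown:
        raise ParameterError(f"unknown stages: {sorted(unknown)}")
    st: dict = {}
    produced: set[str] = set()
    for stage in config.stages:  # run in the order given; deps must be satisfied
        for dep in _DEPS[stage]:
            if dep not in st:
                raise DependencyError(
                    f"stage {stage!r} requires the {dep!r} product; "
                    "run its producing stage first"
                )
        t0 = time.perf_counter()
        _STAGE_FN[stage](config, st)
        n = len(st.get("corpus", [])) if stage == "synth" else (
            st["stm"].X.shape[0] if "stm" in st else 0
        )
        log.info("stage %-8s done in %6.1f s (%d samples)", stage, time.perf_counter() - t0, n)
        produced.add(stage)

    res = PipelineResults(config=config)
    for f in dataclasses.fields(PipelineResults):
        if f.name in st:
            setattr(res, f.name, st[f.name])
    if out_dir is not None:
        ResultsContainer(out_dir).save(res)
    return res


class ResultsContainer:
    """HDF5-backed results store (axis-carrying arrays) with CSV mirrors for
    tables and a JSON provenance record (config, seeds, software version)."""

    def __init__(self, out_dir: str | Path):
        self.dir = Path(out_dir)
        self.h5_path = self.dir / "results.h5"
        self.tables = self.dir / "tables"

    def save(self, res: PipelineResults) -> None:
        self.dir.mkdir(parents=True, exist_ok=True)
        self.tables.mkdir(exist_ok=True)
        with h5py.File(self.h5_path, "w") as f:
            if res.stm is not None:
                res.stm.to_hdf5(f.create_group("stm"))
            if res.statmap is not None:
                g = f.create_group("contrast")
                for name in ("statistic", "p"):
                    g.create_dataset(name, data=getattr(res.statmap, name))
                g.create_dataset("mask", data=res.statmap.mask.astype("u1"))
                g.create_dataset("spectral_axis", data=res.statmap.spectral_axis)
                g.create_dataset("temporal_axis", data=res.statmap.temporal_axis)
                g.attrs["alpha"] = res.statmap.alpha
                g.attrs["n_permutations"] = res.statmap.n_permutations
            if res.overlap_counts is not None:
                f.create_dataset("contrast/overlap_counts", data=res.overlap_counts)
            if res.decode is not None and res.decode.weight_map is not None:
                f.create_dataset("decode/weight_map", data=res.decode.weight_map)
            if res.behavior_corr_map is not None:
                g = f.create_group("behavior")
                g.create_dataset("r", data=res.behavior_corr_map.r)
                g.create_dataset("mask", data=res.behavior_corr_map.mask.astype("u1"))
            if res.plsmap is not None:
                g = f.create_group("pls")
                g.create_dataset("r", data=res.plsmap.r)
                g.create_dataset("mask", data=res.plsmap.mask.astype("u1"))
        for name, df in (
            ("peaks_pos", None if res.peaks_pos is None else res.peaks_pos.peaks),
            ("peaks_neg", None if res.peaks_neg is None else res.peaks_neg.peaks),
            ("vip_report", res.vip_report),
            ("ratings", res.ratings),
            ("comparison_accuracy", None if res.comparison is None else res.comparison.accuracy_table),
        ):
            if df is not None:
                df.to_csv(self.tables / f"{name}.csv", index=name == "comparison_accuracy")
        if res.decode is not None:
            res.decode.accuracy_by_group().to_csv(self.tables / "decode_accuracy.csv")
        prov = {
            "config": _jsonable(res.config.to_dict()),
            "version": __version__,
            "seed": res.config.seed,
        }
        (self.dir / "provenance.json").write_text(json.dumps(prov, indent=2))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def summarize(res: PipelineResults) -> str:
    """Human-readable run summary: hotspot peaks, accuracies, test statistics
    and top VIP features, with coordinates in cyc/kHz and Hz."""
    lines: list[str] = ["vocalstm run summary", "=" * 20]
    empty = True
    if res.statmap is not None:
        empty = False
        lines.append(
            f"contrast: {int(res.statmap.mask.sum())} FDR-significant cells "
            f"(alpha={res.statmap.alpha}, {res.statmap.n_permutations} permutations, "
            f"{res.statmap.n_pairs} pairs)"
        )
        for label, ps in (("song > speech", res.peaks_pos), ("speech > song", res.peaks_neg)):
            if ps is not None and len(ps):
                row = ps.peaks.iloc[0]
                lines.append(
                    f"  {label} peak: {row['spectral_cyc_per_khz']:.2f} cyc/kHz, "
                    f"{row['temporal_hz']:.2f} Hz (t={row['stat']:.1f})"
                )
    if res.overlap_counts is not None:
        lines.append(f"  society overlap: max {int(res.overlap_counts.max())} groups agree")
    if res.kmeans_centroids is not None:
        for i, c in enumerate(res.kmeans_centroids):
            lines.append(f"  k-means centroid {i + 1}: {c[0]:.2f} cyc/kHz, {c[1]:.2f} Hz")
    if res.decode is not None:
        empty = False
        lines.append(
            f"decoding ({res.decode.grouping}-wise, lambda={res.decode.lam}): "
            f"accuracy {res.decode.accuracy_mean:.1f}% +/- {res.decode.accuracy_sd:.1f} (SD); "
            f"sensitivity {np.nanmean(res.decode.fold_sensitivity):.1f}%, "
            f"specificity {np.nanmean(res.decode.fold_specificity):.1f}%"
        )
        if res.wilcoxon is not None:
            w = res.wilcoxon
            lines.append(
                f"  vs chance: W({w.n - 1}) = {w.w:.0f}, p = {w.p:.2g}, "
                f"rank-biserial = {w.rank_biserial:.2f}"
            )
    if res.accuracy_behavior_corr is not None:
        r, p = res.accuracy_behavior_corr
        lines.append(f"behavior: accuracy-rating correlation r = {r:.2f}, p = {p:.2g}")
    if res.comparison is not None:
        c = res.comparison
        lines.append(
            f"feature sets: Friedman chi2({c.accuracy_table.shape[1] - 1}) = "
            f"{c.friedman_chi2:.1f}, p = {c.friedman_p:.2g}, Kendall's W = {c.kendalls_w:.2f}"
        )
        lines.append("  " + ", ".join(
            f"{k}: {v:.1f}%" for k, v in c.accuracy_table.mean().items()
        ))
    if res.vip_report is not None and len(res.vip_report):
        empty = False
        top = res.vip_report.sort_values("vip", ascending=False).head(5)
        feats = ", ".join(f"{r.feature} ({r.vip:.2f})" for r in top.itertuples())
        lines.append(f"top VIP features: {feats}")
    if empty:
        lines.append("(container holds no result groups)")
    return "\n".join(lines)
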