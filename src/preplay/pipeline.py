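"""End-to-end orchestration: simulate -> represent -> intensity -> group.

Wires the synthetic cohort generator, the first-level GLM representation
stage, the top-N Fisher-Z intensity statistic, and the merged-correlation
group statistics into one reproducible run driven by a validated config.
Every results bundle is stamped with the config hash and seed so reruns
can be verified bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator
from scipy import stats as sps

from . import rsa, searchlight as sl, stats
from .representation import (
    RepresentationMap,
    build_design_matrix,
    fit_glm_tmaps,
    select_informative_voxels,
)
from .rsa import RestingSeries
from .synthetic import SyntheticSpec, make_dataset

logger = logging.getLogger("preplay")

__all__ = ["PipelineConfig", "run_all", "load_subject", "config_hash"]

REST_SESSIONS = ("day1", "day2pre", "day2post")


class PipelineConfig(BaseModel):
    """Validated parameterization of a full pipeline run."""

    dataset_dir: str
    out_dir: str
    simulate: bool = True
    spec: dict = Field(default_factory=dict)
    n_top: int | Literal["auto"] = 15
    ntop_grid: list[int] = Field(default_factory=lambda: list(range(10, 81, 5)))
    drop_fraction: float = 0.03
    sidedness_main: Literal["one", "two"] = "one"
    sidedness_compare: Literal["one", "two"] = "two"
    run_searchlight: bool = False
    searchlight_n_top: int = 13
    searchlight_radius: int = 2
    n_permutations: int = 1000
    seed: int = 0

    @field_validator("drop_fraction")
    @classmethod
    def _check_fraction(cls, v):
        if not 0.0 <= v < 1.0:
            raise ValueError("drop_fraction must be in [0, 1)")
        return v

    @field_validator("n_top")
    @classmethod
    def _check_ntop(cls, v):
        if v != "auto" and int(v) < 1:
            raise ValueError("n_top must be >= 1 or 'auto'")
        return v

    def synthetic_spec(self) -> SyntheticSpec:
        params = dict(self.spec)
        params.setdefault("seed", self.seed)
        return SyntheticSpec.from_dict({**SyntheticSpec().to_dict(), **params})


def config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _load_nifti(path: Path) -> np.ndarray:
    if not path.exists():
        raise FileNotFoundError(f"required input missing: {path}")
    return np.asarray(nib.load(str(path)).get_fdata(), dtype=float)


def _load_tsv(path: Path) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(f"required input missing: {path}")
    return pd.read_csv(path, sep="\t", na_values=["N/A"])


def load_subject(sub_dir: Path, n_discard: int) -> dict:
    """Load one subject's volumes and tables from a cohort directory."""
    sub_dir = Path(sub_dir)
    mask = _load_nifti(sub_dir / "mask.nii") > 0.5
    rest = {}
    for name in REST_SESSIONS:
        vol = _load_nifti(sub_dir / f"rest_{name}.nii")
        data = vol[mask].T[n_discard:]  # frames x voxels, lead-in dropped
        rest[name] = RestingSeries(data=data, mask=mask, session=name)
    induced = {}
    for set_name in ("prior", "posterior"):
        events = _load_tsv(sub_dir / f"events_{set_name}.tsv")
        runs = sorted(sub_dir.glob(f"induced_{set_name}_run-*.nii"))
        if not runs:
            raise FileNotFoundError(f"no induced runs for {set_name} in {sub_dir}")
        induced[set_name] = ([_load_nifti(p) for p in runs], events)
    return {
        "mask": mask,
        "rest": rest,
        "induced": induced,
        "ratings": _load_tsv(sub_dir / "ratings.tsv"),
        "associations": _load_tsv(sub_dir / "associations.tsv"),
    }


def extract_tmaps(
    volumes: Sequence[np.ndarray],
    events: pd.DataFrame,
    mask: np.ndarray,
    tr: float,
) -> list[RepresentationMap]:
    """Concatenated-session GLM t-maps, one per sentence."""
    designs = []
    for ses, ev in events.groupby("session", sort=True):
        n_frames = volumes[int(ses)].shape[-1]
        designs.append(build_design_matrix(ev, n_frames, tr))
    return fit_glm_tmaps(list(volumes), designs, mask=mask)


def _subject_intensities(
    data: dict, cfg: PipelineConfig, tr: float, subject: str
) -> tuple[pd.DataFrame, dict]:
    """Represent + intensity stages for one subject."""
    mask = data["mask"]
    tmaps, keep = {}, {}
    for set_name in ("prior", "posterior"):
        volumes, events = data["induced"][set_name]
        maps = extract_tmaps(volumes, events, mask, tr)
        keep[set_name] = select_informative_voxels(maps, cfg.drop_fraction)
        tmaps[set_name] = [
            RepresentationMap(m.sentence_id, m.values[keep[set_name]], None, m.source)
            for m in maps
        ]

    info = {}
    if cfg.n_top == "auto":
        series = data["rest"]["day2pre"]
        sub_series = RestingSeries(
            data=series.data[:, keep["posterior"]], session=series.session
        )
        est = rsa.estimate_ntop(sub_series, tmaps["posterior"], cfg.ntop_grid)
        n_top = est.chosen
        info["ntop_estimate"] = int(n_top)
    else:
        n_top = int(cfg.n_top)

    frames = []
    for session, set_name in (
        ("day1", "prior"),
        ("day2pre", "posterior"),
        ("day2post", "posterior"),
    ):
        series = data["rest"][session]
        sub_series = RestingSeries(
            data=series.data[:, keep[set_name]], session=session
        )
        tab = rsa.intensity_table(sub_series, tmaps[set_name], n_top=n_top)
        tab.insert(0, "subject", subject)
        tab.insert(2, "set", set_name)
        frames.append(tab)
    table = pd.concat(frames, ignore_index=True)

    assoc = data["associations"].set_index("posterior_id")["prior_id"]
    def condition(row):
        if row["set"] == "prior":
            return "prior"
        return "w_prior" if pd.notna(assoc.get(row["sentence_id"])) else "wo_prior"

    table["condition"] = table.apply(condition, axis=1)
    info["n_top"] = int(n_top)
    return table, info


def _merged_result(subs, sidedness) -> dict:
    m = stats.merge_correlations(subs, sidedness=sidedness)
    return {
        "zeta": m.zeta,
        "se": m.se,
        "r_merged": m.r_merged,
        "z": m.z_stat,
        "p_raw": m.p_value,
        "sidedness": m.sidedness,
        "n_subjects": m.n_subjects,
    }


def group_analysis(
    intensity_df: pd.DataFrame, ratings_df: pd.DataFrame, cfg: PipelineConfig
) -> dict:
    """Headline group statistics over an intensity table.

    Covers the four main tests (merged intensity-rating correlation with
    and without prior association, their comparison, the above/below-mean
    split) plus the prior-sentence control and the Day-2-post vs Day-2-pre
    stabilization contrast.  Bonferroni correction spans the two
    conditions of each paired report.
    """
    results: dict = {}
    post_ratings = ratings_df[ratings_df["set"] == "posterior"][
        ["subject", "sentence_id", "rating"]
    ]
    prior_ratings = ratings_df[ratings_df["set"] == "prior"][
        ["subject", "sentence_id", "rating"]
    ]

    day2pre = intensity_df[
        (intensity_df["session"] == "day2pre") & (intensity_df["set"] == "posterior")
    ]
    merged_by_cond = {}
    for cond in ("w_prior", "wo_prior"):
        sel = day2pre[day2pre["condition"] == cond][
            ["subject", "sentence_id", "intensity"]
        ]
        subs = stats.per_subject_correlation(sel, post_ratings, condition=cond)
        merged_by_cond[cond] = stats.merge_correlations(
            subs, sidedness=cfg.sidedness_main
        )
        results[f"{cond}_correlation"] = _merged_result(subs, cfg.sidedness_main)
        results[f"{cond}_correlation"]["per_subject"] = [
            {"subject": s.subject_id, "r": s.r, "n": s.n} for s in subs
        ]
        split = stats.above_below_split(sel, post_ratings, sidedness=cfg.sidedness_main)
        results[f"split_{cond}"] = {
            "t": split.t_stat,
            "p_raw": split.p_value,
            "dof": split.dof,
            "sidedness": split.sidedness,
        }
    for cond in ("w_prior", "wo_prior"):
        results[f"{cond}_correlation"]["p_corrected"] = float(
            stats.bonferroni(results[f"{cond}_correlation"]["p_raw"], 2)
        )
        results[f"split_{cond}"]["p_corrected"] = float(
            stats.bonferroni(results[f"split_{cond}"]["p_raw"], 2)
        )
    z, p = stats.compare_merged(
        merged_by_cond["w_prior"], merged_by_cond["wo_prior"], cfg.sidedness_compare
    )
    results["comparison_w_vs_wo"] = {"z": z, "p": p, "sidedness": cfg.sidedness_compare}

    day1 = intensity_df[
        (intensity_df["session"] == "day1") & (intensity_df["set"] == "prior")
    ][["subject", "sentence_id", "intensity"]]
    prior_subs = stats.per_subject_correlation(day1, prior_ratings, condition="prior")
    results["prior_correlation"] = _merged_result(prior_subs, cfg.sidedness_main)

    # stabilization: Day 2 post vs Day 2 pre mean intensity, paired across subjects
    post_tab = intensity_df[intensity_df["set"] == "posterior"]
    pivot = (
        post_tab.groupby(["subject", "session"])["intensity"].mean().unstack("session")
    )
    res = sps.ttest_rel(pivot["day2post"], pivot["day2pre"], alternative="greater")
    results["stabilization_post_vs_pre"] = {
        "t": float(res.statistic),
        "p": float(res.pvalue),
        "dof": len(pivot) - 1,
        "sidedness": "one",
    }
    return results


def run_all(config: PipelineConfig) -> dict:
    """Execute every enabled stage and write the results bundle.

    Returns the results dict; also writes ``results.json``, the intensity
    table, and per-subject correlation TSVs under ``config.out_dir``.
    Any stage failure propagates with the stage name attached.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dataset_dir = Path(config.dataset_dir)
    spec = config.synthetic_spec()

    stage = "simulate"
    try:
        manifest_path = dataset_dir / "manifest.json"
        if not manifest_path.exists():
            if not config.simulate:
                raise FileNotFoundError(f"no dataset at {dataset_dir} and simulate off")
            logger.info("simulating cohort into %s", dataset_dir)
            make_dataset(spec, dataset_dir)
        manifest = json.loads(manifest_path.read_text())
        n_discard = int(manifest.get("n_discard_frames", 0))
        tr = float(manifest["spec"]["tr_seconds"])

        stage = "represent/intensity"
        tables, ratings_frames, ntop_infos = [], [], {}
        sl_inputs = []
        for sub in manifest["subjects"]:
            logger.info("processing %s", sub)
            data = load_subject(dataset_dir / sub, n_discard)
            table, info = _subject_intensities(data, config, tr, sub)
            tables.append(table)
            ntop_infos[sub] = info
            ratings = data["ratings"].copy()
            ratings.insert(0, "subject", sub)
            ratings_frames.append(ratings)
            if config.run_searchlight:
                sl_inputs.append((sub, data))
        intensity_df = pd.concat(tables, ignore_index=True)
        ratings_df = pd.concat(ratings_frames, ignore_index=True)

        stage = "group"
        results = group_analysis(intensity_df, ratings_df, config)
        results["n_top"] = {s: i["n_top"] for s, i in ntop_infos.items()}

        if config.run_searchlight:
            stage = "searchlight"
            results["searchlight"] = _searchlight_stage(sl_inputs, config, tr)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    results["config"] = config.model_dump()
    results["config_hash"] = config_hash(config)
    results["seed"] = config.seed
    intensity_df.to_csv(out_dir / "intensities.tsv", sep="\t", index=False)
    (out_dir / "results.json").write_text(json.dumps(results, indent=1, sort_keys=True))
    return results


def _searchlight_stage(sl_inputs, config: PipelineConfig, tr: float) -> dict:
    maps, ratings, assoc = [], [], []
    for sub, data in sl_inputs:
        mask = data["mask"]
        volumes, events = data["induced"]["posterior"]
        tmaps = extract_tmaps(volumes, events, mask, tr)
        tvol = np.stack([m.to_volume(fill=0.0) for m in tmaps], axis=-1)
        rest = data["rest"]["day2pre"]
        rest4d = np.zeros(mask.shape + (rest.n_frames,))
        rest4d[mask] = rest.data.T
        smap = sl.searchlight_intensity(
            rest4d, tvol, mask,
            n_top=config.searchlight_n_top, radius=config.searchlight_radius,
        )
        maps.append(smap.masked())
        tab = data["ratings"]
        post = tab[tab["set"] == "posterior"].sort_values("sentence_id")
        ratings.append(post["rating"].to_numpy())
        assoc.append(post["associated"].to_numpy(dtype=bool))
    stat, p = sl.condition_contrast_map(
        maps, ratings, assoc,
        n_permutations=config.n_permutations, seed=config.seed,
    )
    return {
        "n_voxels": int(stat.size),
        "n_significant_fwe05": int(np.nansum(p < 0.05)),
        "max_stat": float(np.nanmax(stat)),
        "min_p": float(np.nanmin(p)),
    }
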