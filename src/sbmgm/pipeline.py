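"""End-to-end orchestration: volumes -> mask -> matrix -> ICA(+ICASSO) ->
Z maps -> artifact flags -> component selection -> loading statistics.

A single YAML config drives the run; every numeric stage is seeded, so a
rerun with the same config reproduces all outputs bitwise.  The slow stage
(repeated ICA) is content-addressed by a hash of the decomposition-relevant
config so the statistics can be re-run without re-decomposition.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import gmio, netmaps, sbmstats, synthcohort
from .errors import ConfigError, SBMError
from .icasso import IcassoICA
from .sbmcore import InfomaxICA, estimate_order_mdl

log = logging.getLogger("sbmgm")

_SCHEMA: dict[str, dict[str, type | tuple]] = {
    "simulate": {
        "enabled": bool, "n_hs": int, "n_mdd": int, "grid_shape": list,
        "voxel_size_mm": (int, float), "k_true": int, "blobs_per_source": int,
        "blob_fwhm_mm": (int, float), "smoothing_fwhm_mm": (int, float),
        "noise_sd": (int, float), "effect_d": dict,
        "cortisol_component": int, "rho_target": (int, float),
        "baseline_factor": (int, float), "seed": int,
    },
    "paths": {"volumes": str, "table": str, "out": str},
    "mask": {"threshold_fraction": (int, float), "explicit": (str, type(None))},
    "ica": {
        "k": (int, str), "learning_rate": (int, float, type(None)),
        "batch_size": (int, type(None)), "anneal_deg": (int, float),
        "anneal_factor": (int, float), "tol": (int, float), "max_iter": int,
        "extended": bool, "seed": int,
        "mdl_subsample": (int, float, type(None)),
    },
    "icasso": {"runs": int},
    "maps": {
        "z_threshold": (int, float), "two_sided": bool, "edge_depth": int,
        "edge_frac": (int, float), "gm_frac": (int, float),
    },
    "selection": {
        "components": list, "roi_mask": (str, type(None)),
        "min_overlap": (int, float, type(None)),
    },
    "stats": {
        "alpha": (int, float), "m_components": (int, type(None)),
        "m_corr": int, "covariate": str, "loading_transform": str,
    },
}

_DEFAULTS: dict[str, dict[str, Any]] = {
    "simulate": {"enabled": False},
    "paths": {"out": "sbm_out"},
    "mask": {"threshold_fraction": 0.2, "explicit": None},
    "ica": {
        "k": "auto", "learning_rate": None, "batch_size": None,
        "anneal_deg": 60.0, "anneal_factor": 0.9, "tol": 1e-6,
        "max_iter": 512, "extended": False, "seed": 0, "mdl_subsample": None,
    },
    "icasso": {"runs": 20},
    "maps": {
        "z_threshold": 2.5, "two_sided": False, "edge_depth": 2,
        "edge_frac": 0.5, "gm_frac": 0.5,
    },
    "selection": {"components": [], "roi_mask": None, "min_overlap": None},
    "stats": {
        "alpha": 0.05, "m_components": None, "m_corr": 2,
        "covariate": "cortisol_nmol_l", "loading_transform": "zscore",
    },
}


@dataclass
class RunConfig:
    """Validated, fully-defaulted pipeline configuration."""

    sections: dict[str, dict[str, Any]] = field(default_factory=dict)

    def __getitem__(self, section: str) -> dict[str, Any]:
        return self.sections[section]

    def fingerprint(self, *sections: str) -> str:
        payload = {s: self.sections[s] for s in (sections or self.sections)}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _validate_dict(raw: dict) -> tuple[RunConfig, list[str]]:
    errors: list[str] = []
    merged: dict[str, dict[str, Any]] = {}
    if not isinstance(raw, dict):
        return RunConfig(), ["config root must be a mapping"]
    for section in raw:
        if section not in _SCHEMA:
            errors.append(f"unknown section {section!r}")
    for section, schema in _SCHEMA.items():
        got = raw.get(section, {})
        if got is None:
            got = {}
        if not isinstance(got, dict):
            errors.append(f"section {section!r} must be a mapping")
            got = {}
        merged[section] = dict(_DEFAULTS.get(section, {}))
        for key, value in got.items():
            if key not in schema:
                errors.append(f"unknown key {section}.{key}")
                continue
            expected = schema[key]
            if isinstance(value, bool) and expected is int:
                errors.append(f"{section}.{key} must be an integer")
                continue
            if not isinstance(value, expected):
                errors.append(
                    f"{section}.{key} has type {type(value).__name__}, "
                    f"expected {expected}"
                )
                continue
            merged[section][key] = value

    # semantic checks (collected, not first-failure)
    ic = merged["icasso"]
    if isinstance(ic.get("runs"), int) and ic["runs"] < 0:
        errors.append("icasso.runs must be >= 0 (0 disables ICASSO)")
    k = merged["ica"].get("k")
    if isinstance(k, str) and k != "auto":
        errors.append('ica.k must be an integer or "auto"')
    if isinstance(k, int) and k < 1:
        errors.append("ica.k must be >= 1")
    mt = merged["mask"].get("threshold_fraction")
    if isinstance(mt, (int, float)) and not 0 <= mt <= 1:
        errors.append("mask.threshold_fraction must lie in [0, 1]")
    st = merged["stats"]
    if st.get("loading_transform") not in ("zscore", "atanh"):
        errors.append('stats.loading_transform must be "zscore" or "atanh"')
    if not merged["simulate"].get("enabled"):
        for key in ("volumes", "table"):
            if key not in merged["paths"]:
                errors.append(
                    f"paths.{key} is required when simulate.enabled is false"
                )
    return RunConfig(sections=merged), errors


def validate_config(path_or_dict: str | Path | dict) -> RunConfig:
    """Load and validate a YAML config; raise :class:`ConfigError` listing
    every problem found (not just the first)."""
    if isinstance(path_or_dict, dict):
        raw = path_or_dict
    else:
        p = Path(path_or_dict)
        if not p.exists():
            raise ConfigError(f"config file not found: {p}")
        raw = yaml.safe_load(p.read_text()) or {}
    config, errors = _validate_dict(raw)
    if errors:
        raise ConfigError(
            "invalid configuration:\n" + "\n".join(f"  - {e}" for e in errors)
        )
    return config


def _sim_config(section: dict[str, Any]) -> synthcohort.SimulationConfig:
    kwargs = {
        k: v for k, v in section.items() if k not in ("enabled",)
    }
    if "grid_shape" in kwargs:
        kwargs["grid_shape"] = tuple(kwargs["grid_shape"])
    if "effect_d" in kwargs:
        kwargs["effect_d"] = {int(k): float(v) for k, v in kwargs["effect_d"].items()}
    return synthcohort.SimulationConfig(**kwargs)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except SBMError as exc:
                raise type(exc)(
                    f"[stage {name}] {exc} "
                    f"(hint: check the '{name}' section of the config)"
                ) from exc
            log.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


def run_pipeline(config: RunConfig | str | Path | dict, out_dir: str | Path | None = None) -> dict:
    """Execute the full analysis and return the run report (also written to
    ``<out>/report.json`` and ``report.md``)."""
    if not isinstance(config, RunConfig):
        config = validate_config(config)
    out = Path(out_dir or config["paths"]["out"])
    out.mkdir(parents=True, exist_ok=True)

    # --- acquire cohort -------------------------------------------------
    if config["simulate"].get("enabled"):
        sim = _sim_config(config["simulate"])
        truth, volumes, table = _stage("simulate")(synthcohort.simulate)(
            sim, out_dir=out / "cohort"
        )
    else:
        table = pd.read_csv(config["paths"]["table"], sep="\t")
        volumes = _stage("load")(gmio.load_cohort)(
            config["paths"]["volumes"], table
        )
        truth = None

    # --- mask + matrix --------------------------------------------------
    explicit = config["mask"]["explicit"]
    explicit_mask = (
        gmio.load_volume(explicit).data.astype(bool) if explicit else None
    )
    mask = _stage("mask")(gmio.make_mask)(
        volumes, config["mask"]["threshold_fraction"], explicit_mask
    )
    matrix = _stage("matrix")(gmio.build_matrix)(volumes, mask)

    # --- order + decomposition (content-addressed cache) ----------------
    ica_cfg = config["ica"]
    if ica_cfg["k"] == "auto":
        k = _stage("order")(estimate_order_mdl)(
            matrix, subsample_fraction=ica_cfg["mdl_subsample"]
        )
    else:
        k = int(ica_cfg["k"])
    runs = config["icasso"]["runs"]
    cache_key = config.fingerprint("simulate", "paths", "mask", "ica", "icasso")
    cache_file = out / "cache" / f"decomposition_{cache_key}.npz"
    if cache_file.exists():
        log.info("stage decompose: cache hit (%s)", cache_file.name)
        blob = np.load(cache_file)
        sources, mixing = blob["sources"], blob["mixing"]
        iq = blob["iq"] if "iq" in blob else None
        stability = None
    else:
        est_cls = IcassoICA if runs >= 2 else InfomaxICA
        kwargs = dict(
            n_components=k,
            learning_rate=ica_cfg["learning_rate"],
            batch_size=ica_cfg["batch_size"],
            anneal_deg=ica_cfg["anneal_deg"],
            anneal_factor=ica_cfg["anneal_factor"],
            tol=ica_cfg["tol"],
            max_iter=ica_cfg["max_iter"],
            extended=ica_cfg["extended"],
            random_state=ica_cfg["seed"],
        )
        if runs >= 2:
            kwargs["runs"] = runs
        est = _stage("decompose")(lambda: est_cls(**kwargs).fit(matrix))()
        sources, mixing = est.components_, est.mixing_
        iq = getattr(est, "iq_", None)
        stability = getattr(est, "stability_report_", None)
        cache_file.parent.mkdir(parents=True, exist_ok=True)
        save = {"sources": sources, "mixing": mixing}
        if iq is not None:
            save["iq"] = iq
        np.savez(cache_file, **save)

    component_ids = list(range(1, k + 1))
    pd.DataFrame(
        mixing, index=matrix.row_ids,
        columns=[f"IC{i}" for i in component_ids],
    ).to_csv(out / "mixing.tsv", sep="\t", index_label="subject_id")
    for i, cid in enumerate(component_ids):
        gmio.save_volume(
            matrix.unflatten(sources[i].astype(np.float32), subject_id=f"IC{cid}"),
            out / "maps" / f"IC{cid}_source.nii.gz",
        )
    if stability is not None:
        (out / "stability.json").write_text(
            json.dumps(stability.to_summary(), indent=2)
        )

    # --- Z maps + artifact flags + selection ----------------------------
    maps_cfg = config["maps"]
    zmaps = [
        netmaps.zscale(
            sources[i], maps_cfg["z_threshold"], component_id=cid,
            two_sided=maps_cfg["two_sided"],
        )
        for i, cid in enumerate(component_ids)
    ]
    gm_reference = truth.mask if truth is not None else None
    labels = [
        netmaps.flag_artifacts(
            z, mask, gm_reference,
            edge_depth=maps_cfg["edge_depth"],
            frac_limits={"edge": maps_cfg["edge_frac"], "gm": maps_cfg["gm_frac"]},
        )
        for z in zmaps
    ]
    sel_cfg = {
        key: val for key, val in config["selection"].items()
        if key in ("components", "min_overlap") and val
    }
    roi_path = config["selection"]["roi_mask"]
    roi_flat = (
        gmio.load_volume(roi_path).data.astype(bool)[mask] if roi_path else None
    )
    selected = _stage("select")(netmaps.select_components)(
        labels, sel_cfg, zmaps=zmaps, roi_mask_flat=roi_flat
    )
    for z in zmaps:
        gmio.save_volume(
            matrix.unflatten(z.thresholded, subject_id=f"IC{z.component_id}_z"),
            out / "maps" / f"IC{z.component_id}_zthr.nii.gz",
        )
    (out / "labels.json").write_text(
        json.dumps(
            [
                {
                    "component_id": lab.component_id,
                    "artifact": lab.artifact_flag,
                    "reasons": lab.artifact_reasons,
                    "selected": lab.selected,
                }
                for lab in labels
            ],
            indent=2,
        )
    )

    # --- statistics ------------------------------------------------------
    st = config["stats"]
    sel_idx = [component_ids.index(cid) for cid in selected]
    loadings_z = sbmstats.standardize_loadings(
        mixing[:, sel_idx], mode=st["loading_transform"]
    )
    groups = table["group"].to_numpy()
    m_comp = st["m_components"] if st["m_components"] else len(selected)
    comp_stats = _stage("stats")(sbmstats.compare_groups)(
        loadings_z, groups, alpha=st["alpha"], m=m_comp, component_ids=selected
    )
    stats_df = sbmstats.stats_table(comp_stats)
    stats_df.to_csv(out / "component_stats.tsv", sep="\t", index=False)

    corr_stats: list = []
    if st["covariate"] in table.columns:
        carried = [
            s.component_id for s in comp_stats if s.significant_after_bonferroni
        ]
        if carried:
            carried_idx = [selected.index(cid) for cid in carried]
            corr_stats = sbmstats.spearman_with_covariate(
                loadings_z[:, carried_idx],
                table[st["covariate"]].to_numpy(),
                groups,
                m=st["m_corr"],
                component_ids=carried,
            )
            sbmstats.corr_table(corr_stats).to_csv(
                out / "covariate_correlations.tsv", sep="\t", index=False
            )
    demo = sbmstats.demographics_tests(table) if "age" in table.columns else None

    report = {
        "config_fingerprint": config.fingerprint(),
        "n_subjects": matrix.n_subjects,
        "n_mask_voxels": matrix.n_voxels,
        "k": k,
        "icasso_runs": runs,
        "iq": [float(v) for v in iq] if iq is not None else None,
        "artifact_components": [
            lab.component_id for lab in labels if lab.artifact_flag
        ],
        "selected_components": selected,
        "component_stats": stats_df.to_dict(orient="records"),
        "covariate_correlations": [
            {
                "component": c.component_id, "group": c.group,
                "rho": c.rho, "p_raw": c.p_raw, "p_adjusted": c.p_adjusted,
            }
            for c in corr_stats
        ],
        "demographics": demo,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    (out / "report.md").write_text(_report_markdown(report))
    return report


def _report_markdown(report: dict) -> str:
    lines = [
        "# SBM run report",
        "",
        f"- config fingerprint: `{report['config_fingerprint']}`",
        f"- subjects: {report['n_subjects']}, mask voxels: {report['n_mask_voxels']}",
        f"- components (K): {report['k']}, ICASSO runs: {report['icasso_runs']}",
    ]
    if report["iq"] is not None:
        lines.append(
            "- Iq per component: "
            + ", ".join(f"{v:.3f}" for v in report["iq"])
        )
    lines += [
        f"- artifact components: {report['artifact_components'] or 'none'}",
        f"- selected components: {report['selected_components']}",
        "",
        "## Loading-coefficient group comparison",
        "",
        "| IC | HS mean±SD | MDD mean±SD | t | p | d | sig |",
        "|---|---|---|---|---|---|---|",
    ]
    for r in report["component_stats"]:
        lines.append(
            f"| {r['component']} | {r['mean_hs']:.2f}±{r['sd_hs']:.2f} "
            f"| {r['mean_mdd']:.2f}±{r['sd_mdd']:.2f} | {r['t']:.2f} "
            f"| {r['p_two_tailed']:.3g} | {r['cohens_d']:.2f} "
            f"| {'*' if r['significant'] else ''} |"
        )
    if report["covariate_correlations"]:
        lines += ["", "## Covariate correlations (Spearman)", ""]
        for c in report["covariate_correlations"]:
            lines.append(
                f"- IC {c['component']} ({c['group']}): rho = {c['rho']:.3f}, "
                f"adjusted p = {c['p_adjusted']:.4f}"
            )
    return "\n".join(lines) + "\n"
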