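"""End-to-end pipeline: simulate -> group -> metrics -> stats -> report.

The pipeline runs either on a synthetic survey (generated in-process from
a seed) or on user-supplied GeoJSON landscape + CSV observations, and
emits grouped CSVs at each chain distance, metric tables, fitted-model
JSON, figures, and a run manifest with file checksums so a re-run under
the same seed is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import demography as demog
from . import grouping, landscape as lsc, stats as st, synthetic as syn

OBS_COLUMNS = ["session", "id", "x_m", "y_m", "zone", "demo_class",
               "in_pouch", "disturbed"]


def mean_individuals_per_session(total_count: int, n_sessions: int,
                                 n_excluded: int = 0) -> float:
    """Mean individuals recorded per session after exclusions, to 1 dp."""
    if n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")
    return round((total_count - n_excluded) / n_sessions, 1)


@dataclass
class PipelineConfig:
    """Single config object driving all stages."""

    seed: int
    out_dir: str = "roosurvey_out"
    chains_m: tuple = (15.0, 30.0, 50.0)
    n_sessions: int = 6
    session_sd: float = 0.0
    landscape_path: str | None = None  # user-supplied mode when set
    observations_path: str | None = None
    greenness_patch_px: int = 400
    make_figures: bool = True

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "seed" not in raw:
            raise ValueError("config must set a seed (file or --seed flag)")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "chains_m" in raw:
            raw["chains_m"] = tuple(float(c) for c in raw["chains_m"])
        return cls(**raw)


@dataclass
class RunManifest:
    """Checksummed inventory of a pipeline run."""

    seed: int
    config_hash: str
    stage_seconds: dict = field(default_factory=dict)
    files: dict = field(default_factory=dict)

    def record(self, path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.files[path.name] = digest

    def save(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"seed": self.seed, "config_hash": self.config_hash,
                 "stage_seconds": self.stage_seconds, "files": self.files},
                fh, indent=2, sort_keys=True,
            )


# ---------------------------------------------------------------------------
# Input validation
# ---------------------------------------------------------------------------

def validate_inputs(observations: pd.DataFrame,
                    landscape: lsc.Landscape) -> list[str]:
    """Schema, enum, containment and id checks; returns violation messages."""
    violations = []
    missing = [c for c in OBS_COLUMNS if c not in observations.columns]
    if missing:
        violations.append(f"missing columns: {missing}")
        return violations
    bad_class = observations.loc[
        ~observations["demo_class"].isin(lsc.DEMO_CLASSES), "demo_class"
    ].unique()
    for b in bad_class:
        violations.append(f"demo_class {b!r} is not one of {lsc.DEMO_CLASSES}")
    known_zones = {z.label for z in landscape.zones}
    for z in observations["zone"].unique():
        if z not in known_zones:
            violations.append(f"observation references unknown zone {z!r}")
    dup = observations.duplicated(subset=["session", "id"])
    if dup.any():
        violations.append(
            f"{int(dup.sum())} duplicate (session, id) pairs, first at row "
            f"{int(np.flatnonzero(dup)[0])}"
        )
    for idx, row in observations.iterrows():
        if row["zone"] not in known_zones:
            continue
        zone = landscape.zone(row["zone"])
        from shapely.geometry import Point

        if not zone.polygon.covers(Point(row["x_m"], row["y_m"])):
            violations.append(
                f"row {idx}: point ({row['x_m']:.1f}, {row['y_m']:.1f}) "
                f"not inside cleared polygon of zone {row['zone']!r}"
            )
    return violations


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: PipelineConfig):
    if cfg.landscape_path and cfg.observations_path:
        land = lsc.Landscape.load(cfg.landscape_path)
        obs = pd.read_csv(cfg.observations_path)
        violations = validate_inputs(obs, land)
        if violations:
            raise ValueError("input validation failed:\n  "
                             + "\n  ".join(violations))
        return land, obs
    sim_cfg = syn.SimulationConfig(seed=cfg.seed, n_sessions=cfg.n_sessions,
                                   session_sd=cfg.session_sd)
    ds = syn.generate_survey(sim_cfg)
    return ds.landscape, ds.observations


def _stage_group(obs: pd.DataFrame, chains) -> dict[float, pd.DataFrame]:
    """Chain-rule partitions per session per chain distance.

    Individuals disturbed during the survey are dropped before grouping
    (they stay in the density table).  Returns per-chain group summary
    tables with a cover_m column added later by the metrics stage.
    """
    undisturbed = obs[obs["disturbed"] != 1]
    out = {}
    for chain in chains:
        frames = []
        for sess, sub in undisturbed.groupby("session"):
            part = grouping.assign_groups(sub, chain)
            s = part.summary()
            s["session"] = sess
            s["chain_m"] = chain
            frames.append(s)
            out.setdefault("_partitions", {})[(chain, sess)] = part
        out[chain] = pd.concat(frames, ignore_index=True)
    return out


def _stage_metrics(obs, land, grouped, cfg: PipelineConfig):
    density = lsc.grazing_density(obs, land)

    for chain in cfg.chains_m:
        g = grouped[chain]
        g["cover_m"] = [
            lsc.distance_to_cover(x, y, land) for x, y in zip(g["cx"], g["cy"])
        ]

    # positioning of vulnerable individuals: 15 m chain only
    chain0 = cfg.chains_m[0]
    records = []
    for (chain, sess), part in grouped["_partitions"].items():
        if chain != chain0:
            continue
        for gid, gmembers in part.groups():
            # front/behind needs a group structure: skip singletons, whose
            # only member coincides with the centre (tie, uninformative)
            if grouping.group_size(gmembers) < 2:
                continue
            rec = lsc.classify_positioning(gmembers, land)
            if not rec.empty:
                rec["session"] = sess
                rec["group_id"] = gid
                records.append(rec)
    positioning = (pd.concat(records, ignore_index=True)
                   if records else pd.DataFrame())

    # per-group composition per chain
    comps = []
    for (chain, sess), part in grouped["_partitions"].items():
        c = demog.composition_table(part)
        c["chain_m"] = chain
        comps.append(c)
    compositions = pd.concat(comps, ignore_index=True)

    # greenness: one simulated patch per group at the zone's mean greenness
    rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, 7])
    profiles = syn.default_profiles()
    green_rows = []
    for chain in cfg.chains_m:
        for _, row in grouped[chain].iterrows():
            prof = profiles.get(row["zone"])
            if prof is None:
                continue
            # patch means vary between groups (pasture heterogeneity);
            # pixel noise adds within-patch texture on top
            patch_mean = float(np.clip(
                rng.normal(prof.mean_greenness, prof.greenness_noise),
                0.01, 0.99))
            patch = syn.simulate_greenness_patch(
                patch_mean, prof.greenness_noise,
                cfg.greenness_patch_px, rng,
            )
            green_rows.append(
                {"chain_m": chain, "session": row["session"],
                 "group_id": row["group_id"], "zone": row["zone"],
                 "size": row["size"], "greenness": lsc.greenness(patch)}
            )
    green = pd.DataFrame(green_rows)
    return density, positioning, compositions, green


def _stage_stats(density, grouped, positioning, compositions, green, cfg):
    fits: dict[str, object] = {}
    fits["density_anova"] = st.density_anova(density)

    moment_rows = []
    for chain in cfg.chains_m:
        g = grouped[chain]
        for zone, sub in g.groupby("zone"):
            sizes = sub["size"].to_numpy(float)
            row = {"zone": zone, "chain_m": chain, "n": len(sizes)}
            try:
                sk = st.dagostino_skewness(sizes)
                row.update(skew=sk.statistic, skew_p=sk.p)
            except ValueError:
                row.update(skew=np.nan, skew_p=np.nan)
            try:
                ku = st.anscombe_kurtosis(sizes)
                row.update(kurtosis=ku.statistic, kurtosis_p=ku.p)
            except ValueError:
                row.update(kurtosis=np.nan, kurtosis_p=np.nan)
            moment_rows.append(row)
    fits["moments"] = pd.DataFrame(moment_rows)

    all_groups = pd.concat([grouped[c] for c in cfg.chains_m],
                           ignore_index=True)
    fits["groupsize_lmm"] = st.groupsize_lmm(all_groups)
    for chain in cfg.chains_m:
        tag = f"{int(chain)}m"
        fits[f"clusteredness_lmm_{tag}"] = st.clusteredness_lmm(grouped[chain])
        fits[f"cover_glmm_{tag}"] = st.groupsize_cover_glmm(grouped[chain])
        comp_c = compositions[compositions["chain_m"] == chain]
        for cls in lsc.DEMO_CLASSES:
            fits[f"demography_lmm_{tag}_{cls}"] = st.demography_lmm(comp_c, cls)
        green_c = green[green["chain_m"] == chain]
        if not green_c.empty:
            a, b = st.greenness_models(green_c)
            fits[f"greenness_zone_lmm_{tag}"] = a
            fits[f"greenness_size_lmm_{tag}"] = b
    if not positioning.empty:
        fits["positioning_gam"] = st.positioning_gam(positioning)
        fits["positioning_proportions"] = lsc.positioning_proportions(positioning)
    return fits


def _stage_report(out, density, grouped, positioning, green, cfg):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    zones = [z for z in lsc.DISTURBANCE_LABELS
             if z in set(density["zone"])]
    figures = []

    fig, axes = plt.subplots(2, 2, figsize=(10, 8))
    density_pos = density[density["density_per_km2"] > 0]
    axes[0, 0].boxplot(
        [np.log(density_pos.loc[density_pos["zone"] == z,
                                "density_per_km2"]) for z in zones],
        tick_labels=zones)
    axes[0, 0].set_ylabel("log density (per km$^2$)")
    g15 = grouped[cfg.chains_m[0]]
    axes[0, 1].boxplot([np.log(g15.loc[g15["zone"] == z, "size"])
                        for z in zones], tick_labels=zones)
    axes[0, 1].set_ylabel("log group size")
    nn = g15.dropna(subset=["mean_nn_m"])
    axes[1, 0].boxplot([np.log(nn.loc[nn["zone"] == z, "mean_nn_m"])
                        for z in zones], tick_labels=zones)
    axes[1, 0].set_ylabel("log mean NN distance (m)")
    if not green.empty:
        gg = green[green["chain_m"] == cfg.chains_m[0]]
        means = [100 * gg.loc[gg["zone"] == z, "greenness"].mean()
                 for z in zones]
        axes[1, 1].bar(zones, means)
        axes[1, 1].set_ylabel("greenness (%)")
        axes[1, 1].set_ylim(min(means) - 1, max(means) + 1)
    fig.tight_layout()
    p = out / "fig_density_size_clustering_greenness.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    figures.append(p)

    if not positioning.empty:
        fig, ax = plt.subplots(figsize=(7, 5))
        props = lsc.positioning_proportions(positioning)
        for z in zones:
            sub = props[props["zone"] == z]
            ax.plot(sub["bracket_lo_m"] + 10, sub["prop_front"],
                    marker="o", label=z)
        ax.set_xlabel("group distance to cover (m, 20 m brackets)")
        ax.set_ylabel("proportion of vulnerable individuals in front")
        ax.legend()
        p = out / "fig_positioning.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        figures.append(p)

    fig, axes = plt.subplots(1, len(cfg.chains_m),
                             figsize=(4 * len(cfg.chains_m), 4),
                             squeeze=False)
    for ax, chain in zip(axes[0], cfg.chains_m):
        g = grouped[chain]
        for z in zones:
            sub = g[g["zone"] == z]
            ax.scatter(np.log(np.maximum(sub["cover_m"], 1.0)),
                       np.log(sub["size"]), s=8, alpha=0.5, label=z)
        ax.set_title(f"chain {int(chain)} m")
        ax.set_xlabel("log distance to cover")
        ax.set_ylabel("log group size")
    axes[0, 0].legend()
    fig.tight_layout()
    p = out / "fig_size_vs_cover.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    figures.append(p)
    return figures


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run_pipeline(cfg: PipelineConfig) -> RunManifest:
    """Run every stage and write artifacts + manifest to ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_text = json.dumps(
        {f: getattr(cfg, f) for f in cfg.__dataclass_fields__},
        sort_keys=True, default=str)
    manifest = RunManifest(
        seed=cfg.seed,
        config_hash=hashlib.sha256(cfg_text.encode()).hexdigest(),
    )

    t0 = time.perf_counter()
    land, obs = _stage_simulate(cfg)
    manifest.stage_seconds["simulate"] = round(time.perf_counter() - t0, 3)
    land.save(out / "landscape.geojson")
    obs.to_csv(out / "observations.csv", index=False)

    t0 = time.perf_counter()
    grouped = _stage_group(obs, cfg.chains_m)
    manifest.stage_seconds["group"] = round(time.perf_counter() - t0, 3)
    for chain in cfg.chains_m:
        tag = f"{int(chain)}m"
        member_rows = []
        for (c, sess), part in grouped["_partitions"].items():
            if c != chain:
                continue
            m = part.membership[["session", "id", "group_id"]].copy()
            m["chain_m"] = chain
            member_rows.append(m)
        pd.concat(member_rows, ignore_index=True).to_csv(
            out / f"groups_members_{tag}.csv", index=False)

    t0 = time.perf_counter()
    density, positioning, compositions, green = _stage_metrics(
        obs, land, grouped, cfg)
    manifest.stage_seconds["metrics"] = round(time.perf_counter() - t0, 3)
    density.to_csv(out / "density.csv", index=False)
    compositions.to_csv(out / "compositions.csv", index=False)
    demog.mean_composition(compositions).to_csv(
        out / "mean_composition.csv", index=False)
    if not positioning.empty:
        positioning.to_csv(out / "positioning.csv", index=False)
    green.to_csv(out / "greenness.csv", index=False)
    for chain in cfg.chains_m:
        grouped[chain].to_csv(out / f"groups_summary_{int(chain)}m.csv",
                              index=False)

    t0 = time.perf_counter()
    fits = _stage_stats(density, grouped, positioning, compositions,
                        green, cfg)
    manifest.stage_seconds["stats"] = round(time.perf_counter() - t0, 3)
    fit_json = {}
    for name, fr in fits.items():
        if isinstance(fr, st.FitResult):
            fit_json[name] = fr.to_json_dict()
        elif isinstance(fr, pd.DataFrame):
            fr.to_csv(out / f"{name}.csv", index=False)
    with open(out / "fits.json", "w") as fh:
        json.dump(fit_json, fh, indent=1, default=float)

    if cfg.make_figures:
        t0 = time.perf_counter()
        _stage_report(out, density, grouped, positioning, green, cfg)
        manifest.stage_seconds["report"] = round(time.perf_counter() - t0, 3)

    for p in sorted(out.iterdir()):
        if p.is_file() and p.suffix in {".csv", ".json", ".geojson"}:
            manifest.record(p)
    manifest.save(out / "manifest.json")
    return manifest
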