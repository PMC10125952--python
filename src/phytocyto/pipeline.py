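"""Configured, logged, reproducible end-to-end runs.

A run is described by a declarative YAML/dict config: which phantom
fields and trait tables to simulate (or which input files to read),
and the parameters of every downstream stage.  ``run_pipeline``
executes the stages in dependency order -- simulate -> segment ->
cellcycle / stage / quantify -> network -- under a single root seed,
and writes a manifest with the parameter hash and a checksum of every
output file, so a rerun with the same config and seed is verifiably
bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cellcycle import DEFAULT_CUTS, profile_sample
from .io import write_micrograph
from .network import (
    build_network,
    fit_window_regression,
    pairwise_correlations,
    significance_screen,
    write_graphml,
)
from .segmentation import measurements_frame, segment_field
from .signals import cross_wall_profile, nuclear_cytoplasmic_split, signals_frame
from .synthetic import (
    DEFAULT_TRAITS,
    PhantomSpec,
    TraitSimSpec,
    gen_aoeb_field,
    gen_nuclei_field,
    gen_signal_field,
    gen_trait_table,
)
from .viability import measure_field_rfi, records_frame, stage_cell, stage_population

__all__ = ["RunConfig", "run_pipeline", "load_config"]

log = logging.getLogger("phytocyto.pipeline")

_FIELD_KINDS = ("nuclei", "aoeb", "signal")


class RunConfig:
    """Validated pipeline configuration.

    Wraps the raw config mapping, checks required fields and exposes
    defaults.  ``seed`` is the root of all randomness in the run.
    """

    def __init__(self, raw: dict):
        if not isinstance(raw, dict):
            raise ValueError("config must be a mapping")
        self.raw = raw
        self.seed = int(raw.get("seed", 0))
        self.fields = raw.get("fields", [])
        for i, f in enumerate(self.fields):
            for key in ("name", "kind"):
                if key not in f:
                    raise ValueError(f"fields[{i}] missing required key {key!r}")
            if f["kind"] not in _FIELD_KINDS:
                raise ValueError(
                    f"fields[{i}].kind {f['kind']!r} not one of {_FIELD_KINDS}"
                )
            if f["kind"] == "signal" and "signal_kind" not in f:
                raise ValueError(f"fields[{i}] (kind=signal) missing 'signal_kind'")
            if f["kind"] == "aoeb":
                cm = f.get("channel_map")
                if cm is None:
                    raise ValueError(
                        f"fields[{i}] (kind=aoeb) missing required key 'channel_map'"
                    )
                if "green" not in cm or "red" not in cm:
                    raise ValueError(
                        f"fields[{i}] channel_map must name 'green' and 'red'"
                    )
        self.traits_cfg = raw.get("traits")
        self.segment_cfg = dict(raw.get("segment", {}))
        self.cellcycle_cfg = dict(raw.get("cellcycle", {}))
        self.stage_cfg = dict(raw.get("stage", {}))
        self.quantify_cfg = dict(raw.get("quantify", {}))
        self.network_cfg = dict(raw.get("network", {}))

    def param_hash(self) -> str:
        blob = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        return RunConfig(yaml.safe_load(fh))


def _field_seed(root: int, index: int) -> int:
    # stable per-field substream, kept in int32 range
    return int((root * 1_000_003 + 7919 * (index + 1)) % (2**31 - 1))


def _build_corr(traits, cfg):
    """Planted correlation matrix, either explicit or single-factor.

    ``factor_loadings`` builds corr = L L^T + diag(1 - L^2), which is
    positive semidefinite for loadings in [-1, 1].
    """
    if cfg is None:
        return None
    if "matrix" in cfg:
        return np.asarray(cfg["matrix"], dtype=float)
    loadings = cfg.get("factor_loadings", {})
    lam = np.array([float(loadings.get(t, 0.0)) for t in traits])
    if np.any(np.abs(lam) > 1):
        raise ValueError("factor loadings must lie in [-1, 1]")
    corr = np.outer(lam, lam)
    np.fill_diagonal(corr, 1.0)
    return corr


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig | dict, out_dir: str | Path) -> dict:
    """Execute all configured stages; return the run manifest.

    Outputs land under ``out_dir`` in a fixed layout (``images/``,
    ``truth/``, ``tables/``, ``network/``, ``manifest.json``).  The
    manifest records the package version, seed, parameter hash and a
    sha256 checksum per output file; identical config + seed reproduce
    every byte.
    """
    if not isinstance(config, RunConfig):
        config = RunConfig(config)
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    (out / "tables").mkdir(exist_ok=True)
    (out / "network").mkdir(exist_ok=True)

    measurements, profiles, stage_rows, signal_frames = [], [], [], []
    viability_frames = []

    # --- simulate + per-field analysis ---------------------------------
    for i, fcfg in enumerate(config.fields):
        name, kind = fcfg["name"], fcfg["kind"]
        spec_kwargs = dict(fcfg.get("spec", {}))
        spec_kwargs.setdefault("seed", _field_seed(config.seed, i))
        for tuple_key in ("image_shape", "ploidy_mixture", "stage_mixture",
                          "nucleus_axes"):
            if tuple_key in spec_kwargs:
                spec_kwargs[tuple_key] = tuple(spec_kwargs[tuple_key])
        spec = PhantomSpec(**spec_kwargs)
        log.info("simulate field %s (kind=%s, seed=%d)", name, kind, spec.seed)

        if kind == "nuclei":
            img, truth = gen_nuclei_field(spec)
        elif kind == "aoeb":
            img, truth = gen_aoeb_field(spec)
        else:
            img, truth = gen_signal_field(
                fcfg["signal_kind"], spec, fcfg.get("region_params")
            )
        write_micrograph(img, out / "images", name)
        truth.write(out / "truth", name)

        if kind == "nuclei":
            seg = config.segment_cfg
            ms, labels, thr = segment_field(
                img, channel="dapi",
                method=seg.get("method", "otsu"),
                threshold=seg.get("threshold"),
                min_area=int(seg.get("min_area", 20)),
                exclude_border=bool(seg.get("exclude_border", True)),
                background=seg.get("background", "median_outside"),
            )
            log.info("segment %s: %d objects (threshold=%s)", name, len(ms), thr)
            measurements.append(measurements_frame(ms, field=name))
            if ms:
                cc = config.cellcycle_cfg
                intens = [m.integrated_density_au for m in ms]
                scale = cc.get("scale")
                prof = profile_sample(
                    intens,
                    cuts=tuple(cc.get("cuts", DEFAULT_CUTS)),
                    scale=None if scale is None else float(scale),
                    band_halfwidth=float(cc.get("band_halfwidth", 0.25)),
                )
                row = dict(field=name, n=prof.n, scale_2c=prof.scale_2c,
                           **{f"phase_{k}": v for k, v in prof.phases.as_dict().items()},
                           **{f"class_{k}": v for k, v in prof.classes.as_dict().items()})
                profiles.append(row)

        elif kind == "aoeb":
            st = config.stage_cfg
            cm = fcfg["channel_map"]
            recs = measure_field_rfi(
                img.channel(cm["green"]), img.channel(cm["red"]),
                truth.masks["nucleus"], truth.masks["nucleolus"],
                background=st.get("background", "median_outside"),
            )
            thresholds = dict(
                t_alive=float(st.get("t_alive", 0.2)),
                t_dead=float(st.get("t_dead", 1.5)),
                t_nco=float(st.get("t_nco", 0.2)),
            )
            recs = [
                dataclasses.replace(
                    r, stage=stage_cell(r.rho_nucleus, r.rho_nucleolus, **thresholds)
                )
                for r in recs
            ]
            viability_frames.append(records_frame(recs, field=name))
            freqs = stage_population(recs)
            stage_rows.append(dict(field=name, n=freqs.n, **freqs.as_dict()))
            log.info("stage %s: %s", name, freqs.as_dict())

        else:  # signal
            q = config.quantify_cfg
            bgr = q.get("background", 0.0)
            raster = img.data[:, :, 0]
            if fcfg["signal_kind"] == "callose":
                sig = cross_wall_profile(raster, truth.masks["cross_wall"],
                                         background=bgr)
            elif fcfg["signal_kind"] == "calcium":
                sig = []
                cells, nucs = truth.masks["cell"], truth.masks["nucleus"]
                for oid in np.unique(cells):
                    if oid == 0:
                        continue
                    sig.extend(nuclear_cytoplasmic_split(
                        raster, cells == oid, nucs == oid,
                        background=bgr, region_id=int(oid),
                    ))
            else:  # evans_blue: per-cell mean absorbance
                from .signals import quantify_region
                cells = truth.masks["cell"]
                sig = [
                    quantify_region(raster, cells == oid, 0.0, int(oid), "whole_cell")
                    for oid in np.unique(cells) if oid > 0
                ]
            signal_frames.append(
                signals_frame(sig, field=name, channel=img.channels[0])
            )

    if measurements:
        pd.concat(measurements).to_csv(out / "tables" / "measurements.csv", index=False)
    if profiles:
        pd.DataFrame(profiles).to_csv(out / "tables" / "cellcycle.csv", index=False)
    if viability_frames:
        pd.concat(viability_frames).to_csv(out / "tables" / "viability.csv", index=False)
    if stage_rows:
        pd.DataFrame(stage_rows).to_csv(out / "tables" / "stage_frequencies.csv", index=False)
    if signal_frames:
        pd.concat(signal_frames).to_csv(out / "tables" / "signals.csv", index=False)

    # --- trait table + network -----------------------------------------
    if config.traits_cfg is not None:
        tc = dict(config.traits_cfg)
        traits = tuple(tc.get("traits", DEFAULT_TRAITS))
        corr = _build_corr(traits, tc.get("corr"))
        tspec = TraitSimSpec(
            traits=traits,
            n_samples=int(tc.get("n_samples", 24)),
            corr=corr,
            effects=dict(tc.get("effects", {})),
            timepoints=tuple(tc.get("timepoints", (0, 1, 2, 3, 4, 5, 6, 7))),
            seed=int(tc.get("seed", _field_seed(config.seed, 9001))),
        )
        table, planted = gen_trait_table(tspec)
        table.to_csv(out / "tables" / "traits.csv", index=False)
        pd.DataFrame(planted, index=list(traits), columns=list(traits)).to_csv(
            out / "truth" / "traits_planted_corr.csv"
        )

        net_cfg = config.network_cfg
        alpha = float(net_cfg.get("alpha", 0.05))
        screen = significance_screen(table, traits=list(traits), alpha=alpha)
        screen.to_csv(out / "network" / "trait_screen.csv")

        window = tuple(net_cfg.get("window", (4.0, 7.0)))
        reg_rows = []
        for t in traits:
            rr = fit_window_regression(table, t, window=window,
                                       model=net_cfg.get("model", "linear"))
            for grp in sorted(rr.r_squared):
                reg_rows.append(dict(
                    trait=t, group=grp, window_lo=rr.window[0],
                    window_hi=rr.window[1], model=rr.model,
                    r_squared=rr.r_squared[grp],
                    coefficients=";".join(f"{c:.10g}" for c in rr.coefficients[grp]),
                    p_u=rr.p_u, p_t=rr.p_t,
                ))
        pd.DataFrame(reg_rows).to_csv(out / "network" / "regressions.csv", index=False)

        r = pairwise_correlations(table, traits=list(traits))
        r.to_csv(out / "network" / "correlations.csv")
        g = build_network(r, screen, alpha=alpha)
        write_graphml(g, out / "network" / "network.graphml")
        edges = pd.DataFrame(
            [dict(source=a, target=b, **d) for a, b, d in g.edges(data=True)],
            columns=["source", "target", "r", "sign", "band"],
        )
        edges.to_csv(out / "network" / "edges.csv", index=False)
        log.info("network: %d nodes, %d edges", g.number_of_nodes(),
                 g.number_of_edges())

    # --- manifest -------------------------------------------------------
    checksums = {
        str(p.relative_to(out)): _sha256(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = dict(
        phytocyto_version=__version__,
        seed=config.seed,
        param_hash=config.param_hash(),
        outputs=checksums,
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
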