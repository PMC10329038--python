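"""Full-trial analysis pipeline: kinetics → bursts → behaviors → info flow
→ pioneers → similarity, with a reproducibility manifest.

The pipeline is a pure function of (input files, configuration, seed):
the global seed deterministically spawns one substream per stage, and the
manifest records input hashes, parameters and package version so a rerun
can be verified bit-for-bit.  Individual stages can be selected via the
``stages`` argument to recompute a subset against existing upstream
outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, behavior_detection, burst_detection, burst_similarity
from . import info_flow as info_flow_mod
from . import kinetics, pioneer_extraction
from .kinetics import _ke_frame
from .tracking_io import read_metadata, read_tracking

__all__ = ["default_params", "run_pipeline"]

KDO_BIN_WIDTHS = (120, 300, 600, 1800, 3600)


def default_params() -> dict:
    return {
        "detrend_window": kinetics.DIURNAL_WINDOW,
        "clamp_eps_frac": 1e-6,
        "s": 2.0,
        "gamma": 1.0,
        "artificial_tol": 300.0,
        "min_trip_gap": behavior_detection.MIN_TRIP_GAP,
        "follow_radius": behavior_detection.FOLLOW_RADIUS,
        "min_follow": behavior_detection.MIN_FOLLOW,
        "orientation_rule": "first-day",
        "kdo_bin_widths": list(KDO_BIN_WIDTHS),
        "te_q": 3,
        "n_shuffles": info_flow_mod.N_SHUFFLES,
        "window_half_width": pioneer_extraction.WINDOW_HALF_WIDTH,
        "nmf_rank": None,             # None -> cophenetic selection
        "nmf_rank_range": [2, 10],
        "nmf_runs_per_rank": 20,
        "nmf_n_iter": pioneer_extraction.N_ITER,
        "nmf_n_restarts": pioneer_extraction.N_RESTARTS,
        "pioneer_mode": "union",
        "amplitude_filter": "matrix-mean",
        "exclude_artificial": True,
        "stress_target": burst_similarity.STRESS_TARGET,
        "mds_max_restarts": burst_similarity.MAX_RESTARTS,
        "n_null_draws": burst_similarity.N_NULL_DRAWS,
        "early_days": 5,
        "late_days": 2,
    }


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _validate(params: dict) -> None:
    if params["s"] <= 1:
        raise ValueError("s must exceed 1")
    if params["gamma"] < 0:
        raise ValueError("gamma must be nonnegative")
    if params["window_half_width"] <= 0:
        raise ValueError("window_half_width must be positive")
    if params["n_shuffles"] < 1 or params["n_null_draws"] < 1:
        raise ValueError("shuffle/draw counts must be positive")


def run_pipeline(
    tracking_path: str | Path,
    metadata_path: str | Path,
    outdir: str | Path,
    seed: int = 0,
    params: dict | None = None,
    ground_truth_path: str | Path | None = None,
    stages: tuple[str, ...] = (
        "kinetics", "bursts", "behaviors", "infoflow", "pioneers", "similarity",
    ),
) -> dict:
    """Run the analysis stages on one trial and write a report bundle.

    Returns the manifest dict.  Raises on the first failing stage, with
    earlier outputs retained and the manifest marking incompleteness.
    """
    p = default_params()
    if params:
        unknown = set(params) - set(p)
        if unknown:
            raise ValueError(f"unknown parameters: {sorted(unknown)}")
        p.update(params)
    _validate(p)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tracking_path = Path(tracking_path)
    metadata_path = Path(metadata_path)
    ss = np.random.SeedSequence(seed)
    stage_seed = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(
            ("kinetics", "bursts", "behaviors", "infoflow", "pioneers", "similarity"),
            ss.spawn(6),
        )
    }
    manifest = {
        "version": __version__,
        "seed": seed,
        "stage_seeds": stage_seed,
        "params": p,
        "inputs": {
            "tracking": _hash_file(tracking_path),
            "metadata": _hash_file(metadata_path),
        },
        "stages": {},
        "complete": False,
    }
    manifest_path = outdir / "manifest.json"

    meta = read_metadata(metadata_path)
    table = read_tracking(tracking_path, meta)
    log: dict[str, dict] = manifest["stages"]

    kg = kinetics.global_ke(table)
    if "kinetics" in stages:
        if len(kg.K) > p["detrend_window"]:
            kd = kinetics.detrend_diurnal(kg, window=p["detrend_window"])
        else:
            kd = kg  # series shorter than the diurnal window: nothing to remove
        kd = kinetics.clamp_positive(kd, eps_frac=p["clamp_eps_frac"])
        kg.to_frame().to_csv(outdir / "k_global.csv", index=False)
        kd.to_frame().to_csv(outdir / "k_detrended.csv", index=False)
        log["kinetics"] = {"n_seconds": len(kg.K), "n_rejected_rows": table.n_rejected}
    else:
        kd = kinetics.clamp_positive(kg, eps_frac=p["clamp_eps_frac"])

    bursts = []
    if "bursts" in stages:
        gaps = burst_detection.rate_to_gaps(kd)
        levels = burst_detection.kleinberg_levels(gaps, s=p["s"], gamma=p["gamma"])
        bursts = burst_detection.extract_bursts(levels, kd)
        bursts = burst_detection.mark_artificial(bursts, meta, tol=p["artificial_tol"])
        pd.DataFrame([asdict(b) for b in bursts]).to_csv(
            outdir / "bursts.csv", index=False
        )
        ibis = burst_detection.inter_burst_intervals(bursts)
        fit_info = None
        if ibis.size >= 10:
            fit = burst_detection.fit_ibi_powerlaw(
                ibis, n_boot=200, seed=stage_seed["bursts"]
            )
            fit_info = asdict(fit)
        log["bursts"] = {"n_bursts": len(bursts), "powerlaw": fit_info}

    dances = follows = trips = roles = None
    if "behaviors" in stages:
        dances = behavior_detection.detect_dances(table)
        follows = behavior_detection.detect_followers(
            table, dances, radius=p["follow_radius"], min_follow=p["min_follow"]
        )
        trips = behavior_detection.detect_trips(table, meta, min_gap=p["min_trip_gap"])
        trips = behavior_detection.flag_orientation_trips(
            trips, meta, rule=p["orientation_rule"]
        )
        roles = behavior_detection.label_burst_roles(bursts, trips, dances, follows)
        dances.to_csv(outdir / "dances.csv", index=False)
        follows.to_csv(outdir / "follows.csv", index=False)
        trips.to_csv(outdir / "trips.csv", index=False)
        roles.to_csv(outdir / "roles.csv", index=False)
        log["behaviors"] = {
            "n_dances": len(dances), "n_follows": len(follows), "n_trips": len(trips),
        }

    if "infoflow" in stages and dances is not None:
        kdo_by_width = {
            w: kinetics.bin_kdo(kg, dances, trips, w)
            for w in p["kdo_bin_widths"]
        }
        flows = info_flow_mod.kdo_scan(
            kdo_by_width, q=p["te_q"], n_shuffles=p["n_shuffles"],
            seed=stage_seed["infoflow"],
        )
        flows.to_csv(outdir / "kdo_flows.csv", index=False)
        log["infoflow"] = {"n_rows": len(flows)}

    pm = None
    pioneer_sets: dict[int, set] = {}
    if "pioneers" in stages and bursts:
        ke = _ke_frame(table)
        rng = np.random.default_rng(stage_seed["pioneers"])
        sidecar = {}
        usable = [
            b for b in bursts if not (p["exclude_artificial"] and b.artificial)
        ]
        for b in usable:
            window = pioneer_extraction.extract_window(
                table, b, half_width=p["window_half_width"], ke=ke
            )
            if p["nmf_rank"] is None:
                r = pioneer_extraction.select_rank(
                    window.A, tuple(p["nmf_rank_range"]),
                    runs_per_rank=p["nmf_runs_per_rank"],
                    n_iter=p["nmf_n_iter"], seed=rng,
                )
            else:
                r = int(p["nmf_rank"])
            res = pioneer_extraction.run_nmf(
                window.A, r, n_iter=p["nmf_n_iter"],
                n_restarts=p["nmf_n_restarts"], seed=rng, track_loss=False,
            )
            pioneer_sets[b.burst_id] = pioneer_extraction.classify_pioneers(
                res, b, window, mode=p["pioneer_mode"],
                amplitude_filter=p["amplitude_filter"],
            )
            sidecar[str(b.burst_id)] = {
                "rank": r, "kl_loss": res.kl_loss,
                "n_pioneers": len(pioneer_sets[b.burst_id]),
                "truncated_window": window.truncated,
            }
        pm = pioneer_extraction.build_pioneer_matrix(pioneer_sets, table.roster)
        pm.to_csv(outdir / "pioneer_matrix.csv")
        (outdir / "pioneers.json").write_text(json.dumps(sidecar, indent=1))
        if roles is not None:
            per_burst, trial = pioneer_extraction.role_overlap(
                pioneer_sets, roles, table.roster
            )
            per_burst.to_csv(outdir / "role_overlap.csv", index=False)
            (outdir / "role_overlap_trial.json").write_text(json.dumps(trial, indent=1))
        log["pioneers"] = {
            "n_bursts_analyzed": len(pioneer_sets),
            "mean_pioneers": float(np.mean([len(s) for s in pioneer_sets.values()]))
            if pioneer_sets else 0.0,
        }
        if ground_truth_path is not None:
            gt = json.loads(Path(ground_truth_path).read_text())
            planted = {
                int(k): {gt["bee_ids"][i] for i in v}
                for k, v in gt.get("planted", {}).items()
            }
            recovery = _recovery_table(bursts, pioneer_sets, planted)
            recovery.to_csv(outdir / "pioneer_recovery.csv", index=False)
            log["pioneers"]["mean_recovery_jaccard"] = (
                float(recovery["jaccard"].mean()) if len(recovery) else None
            )

    if "similarity" in stages and pm is not None and int(pm.to_numpy().sum()) > 0:
        try:
            dm = burst_similarity.jaccard_distances(pm)
        except ValueError as exc:
            log["similarity"] = {"skipped": str(exc)}
        else:
            emb = burst_similarity.nmds_embed(
                dm, stress_target=p["stress_target"],
                max_restarts=p["mds_max_restarts"],
                seed=stage_seed["similarity"],
            )
            coords = pd.DataFrame(
                {
                    "burst_id": list(emb.ids),
                    "mds1": emb.coords[:, 0],
                    "mds2": emb.coords[:, 1],
                }
            )
            coords["stress_flag"] = not emb.converged
            coords.to_csv(outdir / "embedding.csv", index=False)
            log["similarity"] = {
                "stress": emb.stress, "converged": emb.converged,
                "n_excluded_bursts": len(dm.excluded),
            }

    manifest["complete"] = True
    manifest_path.write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


def _recovery_table(bursts, pioneer_sets, planted) -> pd.DataFrame:
    """Jaccard between detected pioneer sets and planted ground truth.

    Each burst is matched to the nearest planted event time (by peak)."""
    rows = []
    if not planted:
        return pd.DataFrame(columns=["burst_id", "event_time", "jaccard"])
    event_times = np.array(sorted(planted))
    for b in bursts:
        if b.burst_id not in pioneer_sets:
            continue
        nearest = event_times[np.argmin(np.abs(event_times - b.peak_t))]
        truth = planted[int(nearest)]
        found = pioneer_sets[b.burst_id]
        union = truth | found
        rows.append(
            dict(
                burst_id=b.burst_id, event_time=int(nearest),
                jaccard=(len(truth & found) / len(union)) if union else np.nan,
            )
        )
    return pd.DataFrame(rows)
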