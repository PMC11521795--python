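"""File formats, session bundles and the end-to-end pipeline driver.

Tables are UTF-8 CSV with a header row and a leading ``# schema=...``
comment line; nested model objects go to JSON; configuration is YAML.
Every loader validates its schema and reports all violations at once.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, coding, decoding, networks, population, synthetic, units
from .behavior import ZONES, BehaviorSession

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "strinet/1"

SCHEMAS = {
    "spikes": ["session_id", "unit_id", "time_s"],
    "zones": ["time_s", "zone_id"],
    "units": ["unit_id", "log_rate", "pv_us", "w_us"],
    "paths": ["trial_id", "label", "correct", "start_s", "end_s"],
}


class SchemaError(ValueError):
    pass


@dataclass
class SessionBundle:
    session_id: str
    duration: float
    spikes: pd.DataFrame  # session_id, unit_id, time_s
    zones: pd.DataFrame  # time_s, zone_id
    unit_features: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)

    def spike_trains(self) -> dict[int, np.ndarray]:
        return {
            int(uid): np.sort(grp["time_s"].to_numpy(dtype=float))
            for uid, grp in self.spikes.groupby("unit_id")
        }

    def behavior_session(self) -> BehaviorSession:
        timeline = list(
            zip(self.zones["time_s"].astype(float), self.zones["zone_id"].astype(str))
        )
        session = BehaviorSession(
            session_id=self.session_id, duration=self.duration, zone_timeline=timeline
        )
        session.traversals = behavior.classify_paths(timeline)
        session.validate()
        return session


def write_table(df: pd.DataFrame, path: str | Path, name: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# schema={SCHEMA_VERSION}/{name}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def load_session_bundle(
    spikes_path: str | Path,
    zones_path: str | Path,
    units_path: str | Path | None = None,
    duration: float | None = None,
    session_id: str | None = None,
) -> SessionBundle:
    """Load and validate a session from its CSV tables.

    Unsorted spike times are auto-sorted with a warning; unknown zone ids
    and missing columns are hard errors, all reported together.
    """
    spikes = read_table(spikes_path)
    zones = read_table(zones_path)
    features = read_table(units_path) if units_path else None

    errors: list[str] = []
    for name, df in (("spikes", spikes), ("zones", zones)):
        missing = [c for c in SCHEMAS[name] if c not in df.columns]
        if missing:
            errors.append(f"{name}: missing column(s) {missing}")
    if features is not None:
        missing = [c for c in SCHEMAS["units"] if c not in features.columns]
        if missing:
            errors.append(f"units: missing column(s) {missing}")
    if not errors:
        bad_zones = set(zones["zone_id"].astype(str)) - set(ZONES)
        if bad_zones:
            errors.append(f"zones: unknown zone id(s) {sorted(bad_zones)}")
        if features is not None:
            orphans = set(spikes["unit_id"]) - set(features["unit_id"])
            if orphans:
                errors.append(f"spikes reference unknown unit id(s) {sorted(orphans)}")
    if errors:
        raise SchemaError("; ".join(errors))

    times = spikes["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(times) < 0):
        logger.warning("spike times not sorted; auto-sorting")
        spikes = spikes.sort_values(["unit_id", "time_s"], kind="stable").reset_index(drop=True)

    sid = session_id or str(spikes["session_id"].iloc[0]) if len(spikes) else "session"
    dur = duration if duration is not None else float(
        max(times.max() if times.size else 0.0, zones["time_s"].max()) + 1.0
    )
    if times.size and (times.min() < 0 or times.max() >= dur):
        raise SchemaError("spike times outside [0, duration)")
    return SessionBundle(
        session_id=sid, duration=dur, spikes=spikes, zones=zones, unit_features=features
    )


def write_session_bundle(
    out_dir: str | Path,
    session: BehaviorSession,
    trains: dict[int, np.ndarray],
    unit_features: pd.DataFrame | None = None,
    manifest: synthetic.GroundTruthManifest | None = None,
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spikes = pd.DataFrame(
        [
            (session.session_id, uid, t)
            for uid, train in sorted(trains.items())
            for t in train
        ],
        columns=SCHEMAS["spikes"],
    )
    zones = pd.DataFrame(session.zone_timeline, columns=SCHEMAS["zones"])
    write_table(spikes, out / "spikes.csv", "spikes")
    write_table(zones, out / "zones.csv", "zones")
    if unit_features is not None:
        write_table(unit_features, out / "units.csv", "units")
    if manifest is not None:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest.to_dict(), fh, indent=1)


PIPELINE_STAGES = (
    "behavior",
    "coding",
    "population",
    "classify_units",
    "sync",
    "networks",
    "decoding",
)

_DEPENDENCIES = {
    "coding": ("behavior",),
    "population": ("behavior",),
    "sync": ("behavior",),
    "networks": ("behavior",),
    "decoding": ("behavior", "coding", "networks"),
}


def run_pipeline(
    bundle: SessionBundle,
    out_dir: str | Path,
    stages: tuple[str, ...] = PIPELINE_STAGES,
    seed: int = 0,
    n_perm: int = 2000,
) -> dict[str, object]:
    """Run the analysis stages in order and write their output tables.

    Stage dependencies are checked before any computation; reruns with the
    same inputs and seed are byte-identical.
    """
    for st in stages:
        for dep in _DEPENDENCIES.get(st, ()):
            if dep not in stages:
                raise ValueError(f"stage {st!r} requires {dep!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict[str, object] = {}
    session = bundle.behavior_session()
    trains = bundle.spike_trains()
    train_list = [trains[k] for k in sorted(trains)]

    if "behavior" in stages:
        paths = pd.DataFrame(
            [
                (tr.trial_id, tr.label, tr.correct, tr.start, tr.end)
                for tr in session.traversals
            ],
            columns=SCHEMAS["paths"],
        )
        write_table(paths, out / "paths.csv", "paths")
        windows = behavior.extract_event_windows(session)
        events = pd.DataFrame(
            [(w.event, w.start, w.end) for w in windows],
            columns=["event", "start_s", "end_s"],
        )
        write_table(events, out / "events.csv", "events")
        results["behavior"] = {"session": session, "windows": windows}

    coding_tables = []
    if "coding" in stages:
        windows = results["behavior"]["windows"]
        for mode in coding.MODES:
            try:
                tab = coding.detect_coding_neurons(trains, session, mode, windows=windows)
            except ValueError as exc:
                logger.warning("coding mode %s skipped: %s", mode, exc)
                continue
            coding_tables.append(tab)
        coding_df = pd.concat(coding_tables, ignore_index=True)
        write_table(coding_df, out / "coding.csv", "coding")
        results["coding"] = coding_df

    if "population" in stages:
        windows = results["behavior"]["windows"]
        rows = []
        for uid, sp in trains.items():
            f = population.bin_firing_rates(sp, windows)
            z = population.zscore_profile(f)
            if z is None:
                continue
            for t, (ft, zt) in enumerate(zip(f, z)):
                rows.append((uid, t, ft, zt))
        zdf = pd.DataFrame(rows, columns=["unit_id", "bin", "f_hz", "z"])
        write_table(zdf, out / "zscores.csv", "zscores")
        if len(zdf):
            ent = population.zscore_entropy(zdf["z"].to_numpy())
            write_table(
                pd.DataFrame([{"n": ent.total, "entropy_nats": ent.value}]),
                out / "entropy.csv",
                "entropy",
            )
        results["population"] = zdf

    if "classify_units" in stages and bundle.unit_features is not None:
        typed, summary = units.classify_units(bundle.unit_features)
        write_table(typed, out / "unit_types.csv", "unit_types")
        results["classify_units"] = typed

    if "sync" in stages:
        from . import sync as sync_mod

        windows = results["behavior"]["windows"]
        rows = []
        for inter in ("A", "B"):
            trials = [(w.start, w.end) for w in windows if w.event == inter]
            uids = sorted(trains)
            for i, ua in enumerate(uids):
                for ub in uids[i + 1 :]:
                    res = sync_mod.permutation_pvalue(
                        trains[ua], trains[ub], trials, n_perm=n_perm,
                        seed=seed, intersection=inter, pair=(ua, ub),
                    )
                    if res is not None:
                        rows.append(
                            (ua, ub, inter, res.n_trials, res.observed, res.p_value)
                        )
        sdf = pd.DataFrame(
            rows, columns=["unit_a", "unit_b", "intersection", "n_trials", "count", "p"]
        )
        write_table(sdf, out / "sync_pairs.csv", "sync_pairs")
        results["sync"] = sdf

    if "networks" in stages:
        cond = networks.build_condition_intervals(session.traversals)
        fitted = {}
        for label, ivs in cond.intervals.items():
            if cond.duration(label) <= 0:
                continue
            fitted[label] = networks.fit_hawkes_network(train_list, ivs)
        if fitted:
            threshold, adj = networks.interaction_graph(list(fitted.values()))
            payload = {
                "threshold": threshold,
                "conditions": {
                    lab: {
                        "mu": p.mu.tolist(),
                        "a": p.a.tolist(),
                        "strengths": p.strengths().tolist(),
                        "adjacency": adj[i].tolist(),
                    }
                    for i, (lab, p) in enumerate(fitted.items())
                },
            }
            with open(out / "networks.json", "w") as fh:
                json.dump(payload, fh)
            edge_rows = []
            for i, (lab, p) in enumerate(fitted.items()):
                s = p.strengths()
                for m in range(p.n_units):
                    for n in range(p.n_units):
                        edge_rows.append(
                            (bundle.session_id, lab, m, n, s[m, n], int(adj[i][m, n]))
                        )
            write_table(
                pd.DataFrame(
                    edge_rows,
                    columns=["session", "condition", "source", "target", "strength", "binary"],
                ),
                out / "edges.csv",
                "edges",
            )
        results["networks"] = fitted

    if "decoding" in stages:
        eligible, reasons = decoding.session_eligibility(
            session.traversals, results["coding"]
        )
        if not eligible:
            write_table(
                pd.DataFrame([{"session": bundle.session_id, "eligible": False,
                               "reasons": "; ".join(reasons)}]),
                out / "decoding.csv",
                "decoding",
            )
            results["decoding"] = None
        else:
            dec_rows = []
            for model in ("poisson", "hawkes"):
                res = decoding.session_decoding_power(
                    train_list, session.traversals, model=model,
                    session_id=bundle.session_id, seed=seed,
                )
                dec_rows.append(res)
            ddf = decoding.decoding_table(dec_rows)
            ddf.insert(1, "eligible", True)
            write_table(ddf, out / "decoding.csv", "decoding")
            results["decoding"] = dec_rows

    run_manifest = {
        "schema": SCHEMA_VERSION,
        "session": bundle.session_id,
        "stages": list(stages),
        "seed": seed,
        "config_hash": hashlib.sha256(
            json.dumps(
                {"session": bundle.session_id, "stages": list(stages), "seed": seed},
                sort_keys=True,
            ).encode()
        ).hexdigest(),
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(run_manifest, fh, indent=1)
    return results
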