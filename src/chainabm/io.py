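"""Result serialization, replay manifests and state snapshots."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import pandas as pd

from .lattice import Grid, SiteState
from .agents import Role
from .simulate import Simulation

RUN_COLUMNS = ["seed", "model", "persistence", "steps",
               "termination_reason", "final_centroid_x"]


def write_results(records: pd.DataFrame, summary, out_dir, *,
                  config=None, master_seed=None) -> dict:
    """Write per-run records, the replicate summary and a replay manifest.

    ``records`` is the per-run DataFrame from
    :func:`chainabm.sweep.run_replicates` (``return_raw=True``);
    ``summary`` the matching :class:`~chainabm.sweep.ReplicateSummary`.
    Produces ``runs.csv``, ``summary.csv`` and ``manifest.json`` under
    ``out_dir`` and returns their paths.  A results file can be exactly
    regenerated from its manifest (same code version, same seeds).
    """
    if records is None or len(records) == 0:
        raise ValueError("no records to write")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    runs_path = out / "runs.csv"
    records.to_csv(runs_path, index=False, columns=RUN_COLUMNS)
    summary_path = out / "summary.csv"
    pd.DataFrame([dataclasses.asdict(summary)]).to_csv(summary_path,
                                                       index=False)
    manifest = {
        "master_seed": master_seed,
        "n_replicates": int(len(records)),
        "replicate_seeds": [int(s) for s in records["seed"]],
        "config": config.to_dict() if config is not None else None,
    }
    blob = json.dumps(manifest, sort_keys=True).encode()
    manifest["config_sha256"] = hashlib.sha256(blob).hexdigest()
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return {"runs": runs_path, "summary": summary_path,
            "manifest": manifest_path}


def render_snapshot(sim: Simulation, path=None, mode: str = "text",
                    protrusions: bool | None = None):
    """Render the current simulation state.

    Text mode emits one character per site ('#' Closed, '.' Open, 'L'
    Leader, 'F' Follower) and round-trips through
    :meth:`chainabm.lattice.Grid.from_text`.  PNG mode follows the same
    legend in color (Closed grey, Open white, Followers blue, Leaders
    red) and draws extended protrusions as rays for the Contact and
    Hybrid Models.  Returns the text, or the written path.
    """
    if protrusions is None:
        protrusions = sim.model != "ecm"
    if mode == "text":
        chars = [list(row) for row in sim.grid.to_text().splitlines()]
        for a in sim.agents:
            x, y = a.position
            chars[y][x] = "L" if a.role == Role.LEADER else "F"
        text = "\n".join("".join(row) for row in chars)
        if path is not None:
            Path(path).write_text(text + "\n")
            return Path(path)
        return text
    if mode != "png":
        raise ValueError(f"unknown snapshot mode {mode!r}")
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap
    img = sim._sites.T.copy()
    fig, ax_ = plt.subplots(figsize=(10, 3.2))
    ax_.imshow(img, origin="upper", interpolation="nearest",
               cmap=ListedColormap(["0.55", "white", "white"]), vmin=0,
               vmax=2)
    for a in sim.agents:
        x, y = a.position
        color = "tab:red" if a.role == Role.LEADER else "tab:blue"
        if protrusions:
            for p in a.protrusions:
                sx, sy = p.sites((x, y))[-1] if p.length else (x, y)
                ax_.plot([x, sx], [y, sy], color=color, lw=0.8, alpha=0.7)
        ax_.add_patch(plt.Rectangle((x - 0.5, y - 0.5), 1, 1, color=color))
    ax_.set_xlabel("x (proximal → distal)")
    ax_.set_ylabel("y")
    ax_.set_title(f"{sim.model} model, t = {sim.time}")
    fig.tight_layout()
    path = Path(path if path is not None else f"snapshot_t{sim.time}.png")
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def read_raster(text_or_path) -> Grid:
    """Read a text raster (from :func:`render_snapshot` or
    :meth:`Grid.to_text`) back into a Grid; agent glyphs become Occupied
    sites."""
    s = str(text_or_path)
    if "\n" not in s and len(s) < 4096 and Path(s).exists():
        return Grid.from_text(Path(s).read_text())
    return Grid.from_text(s)
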