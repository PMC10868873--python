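"""Run configuration and report emission.

A :class:`RunConfig` pins down everything a reproducible analysis run needs:
the model source, the input/response pair, the window, thresholds, solver
tolerances and the t*-grid cap.  :func:`run_analysis` executes the pipeline
and writes a report bundle (CSV series, JSON classification report, run
manifest, optional plots) to the output directory.  The pipeline is fully
deterministic, so identical configurations produce byte-identical CSVs.
"""

from __future__ import annotations

import json
import platform
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .classify import run_classification
from .experiment import IOExperiment
from .fixtures import fixture
from .network import ReactionNetwork, load_network
from .sensitivity import interim_plateau

__all__ = ["RunConfig", "run_analysis"]


@dataclass
class RunConfig:
    """Configuration of one index-analysis run.

    Exactly one of ``fixture_name`` / ``model_json`` / ``model_sbml`` selects
    the model.  For non-fixture sources the input/response species names and
    the input magnitude are required; the baseline state is the model file's
    initial state.
    """

    fixture_name: str | None = None
    scenario: int | None = None
    model_json: str | None = None
    model_sbml: str | None = None
    input_species: str | None = None
    response_species: str | None = None
    input_magnitude: float | None = None
    t0: float = 0.0
    t_end: float = 10.0
    delta_y: float = 0.10
    delta_x: float = 0.10
    rtol: float = 1e-8
    atol: float = 1e-10
    grid_cap: int | None = 150
    outdir: str = "irindex_report"
    plot: bool = False

    def __post_init__(self):
        sources = [s is not None for s in (self.fixture_name, self.model_json, self.model_sbml)]
        if sum(sources) != 1:
            raise ValueError("exactly one model source must be given (fixture, JSON or SBML)")
        for name in ("delta_y", "delta_x"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be a fraction in (0, 1), got {v}")

    def resolve(self) -> tuple[ReactionNetwork, IOExperiment]:
        if self.fixture_name is not None:
            net, exp = fixture(self.fixture_name, self.scenario)
            exp = exp.with_thresholds(self.delta_y, self.delta_x)
            return net, exp
        if self.model_json is not None:
            net = load_network(self.model_json)
        else:
            from .sbml import read_sbml

            net = read_sbml(self.model_sbml)
        if self.input_species is None or self.response_species is None:
            raise ValueError("input and response species are required for file models")
        if self.input_magnitude is None:
            raise ValueError("input magnitude is required for file models")
        exp = IOExperiment(
            input_species=net.index(self.input_species),
            response_species=net.index(self.response_species),
            input_magnitude=self.input_magnitude,
            baseline_state=net.initial_state,
            t0=self.t0,
            t_end=self.t_end,
            delta_y=self.delta_y,
            delta_x=self.delta_x,
        )
        return net, exp

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yml", ".yaml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)


def run_analysis(config: RunConfig, log=print) -> Path:
    """Execute the full pipeline and write the report bundle.

    Returns the output directory.  Raises before any computation if the
    output directory cannot be created/written.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    probe = outdir / ".write_probe"
    try:
        probe.write_text("")
    finally:
        if probe.exists():
            probe.unlink()

    started = time.time()
    net, exp = config.resolve()
    log(f"model: n={net.n} species, M={net.M} reactions")

    report, art = run_classification(
        net,
        exp,
        rtol=config.rtol,
        atol=config.atol,
        grid_cap=config.grid_cap,
        log=lambda msg: log(f"  {msg}"),
    )

    ref = art["reference"]
    ref.to_frame(net.species).to_csv(outdir / "reference_trajectory.csv", index=False,
                                     lineterminator="\n")
    nir = art["nir"]
    frame = nir.to_frame()
    frame["sum_ir"] = art["sum_ir"]
    frame.to_csv(outdir / "nir.csv", index=False, lineterminator="\n")
    for kind, per_species in art["class_indices"].items():
        if not per_species:
            continue
        merged = None
        for name, series in per_species.items():
            df = series.to_frame().rename(columns={name: name})
            merged = df if merged is None else merged.merge(df, on="t_star")
        merged.to_csv(outdir / f"classification_{kind}.csv", index=False,
                      lineterminator="\n")
    report_dict = report.to_dict()
    report_dict["nir_summary"] = nir.summary()
    (outdir / "classification_report.json").write_text(
        json.dumps(report_dict, indent=2, sort_keys=True) + "\n"
    )
    report.to_frame().to_csv(outdir / "classification_report.csv", index=False,
                             lineterminator="\n")

    if config.plot:
        _plot_nir(nir, outdir / "nir.png")

    manifest = {
        "config": asdict(config),
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "scipy": __import__("scipy").__version__,
        "t_grid_points": int(len(art["t_grid"])),
        "wall_clock_s": round(time.time() - started, 3),
        "labels": report.labels,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    log(f"report written to {outdir} ({manifest['wall_clock_s']} s)")
    return outdir


def _plot_nir(nir, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for s in nir.species:
        ax.plot(nir.t_grid, 100 * nir.column(s), label=s)
    ax.axhline(10.0, color="grey", ls=":", lw=1)
    ax.set_xlabel("t* (min)")
    ax.set_ylabel("nir (%)")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
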