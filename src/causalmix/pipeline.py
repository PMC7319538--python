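"""End-to-end pipeline: load → (Pref-Div) → (StEPS) → MGM → PC-Stable → export.

Given a :class:`RunConfig`, :func:`run_pipeline` produces four artifacts
under the configured prefix: ``<prefix>.undirected.sif`` (the mixed
graphical model), ``<prefix>.cpdag.sif`` and ``<prefix>.cpdag.json`` (the
oriented output), and ``<prefix>.log`` (every parameter, seed and test
count needed to reproduce the run byte-for-byte).  A failure in any stage
raises :class:`PipelineError` naming the stage; artifacts written before
the failure are renamed with a ``.partial`` suffix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .dataset import nonparanormal_transform, read_mixed_table
from .graph import write_cytoscape_json, write_sif
from .pcstable import mgm_pcstable
from .prefdiv import PrefDivConfig, prefdiv_select

logger = logging.getLogger("causalmix")

_STAGES = ("load", "prefdiv", "steps", "mgm", "pcstable", "export")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of one pipeline run (flat key=value file or flags)."""

    input: str
    output_prefix: str
    delimiter: str = "\t"
    max_levels: int = 5
    nonparanormal: bool = False
    # Pref-Div (optional; disabled when target is None)
    prefdiv_target: str | None = None
    prefdiv_num_select: int = 10
    prefdiv_cluster: bool = False
    prefdiv_tau: float | str = "auto"
    prefdiv_keep: tuple[str, ...] = ()
    # penalties: explicit triple or StEPS (exactly one)
    use_steps: bool = False
    lambda_cc: float = 0.25
    lambda_cd: float = 0.25
    lambda_dd: float = 0.25
    steps_gamma: float = 0.05
    steps_subsamples: int = 20
    # PC-Stable
    alpha: float = 0.05
    max_depth: int | None = None
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> "RunConfig":
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        return self


def stage_seed(seed: int, stage: str) -> int:
    """Per-stage RNG seed forked from the run seed by a fixed stage label,
    so toggling one stage never changes another stage's stream."""
    idx = _STAGES.index(stage)
    return int(np.random.SeedSequence([seed, idx]).generate_state(1)[0] % (2 ** 31))


def _load_config_file(path: str | Path) -> dict:
    """Flat key = value text config; '#' starts a comment."""
    out: dict = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        out[key] = val
    return out


def config_from_file(path: str | Path, **overrides) -> RunConfig:
    raw = _load_config_file(path)
    kwargs: dict = {}
    bools = {"nonparanormal", "use_steps", "prefdiv_cluster"}
    ints = {"max_levels", "prefdiv_num_select", "steps_subsamples", "seed", "max_depth"}
    floats = {"lambda_cc", "lambda_cd", "lambda_dd", "steps_gamma", "alpha"}
    for key, val in raw.items():
        if key in bools:
            kwargs[key] = val.lower() in ("1", "true", "yes")
        elif key in ints:
            kwargs[key] = int(val)
        elif key in floats:
            kwargs[key] = float(val)
        elif key == "prefdiv_keep":
            kwargs[key] = tuple(v for v in val.split(",") if v)
        elif key == "prefdiv_tau":
            kwargs[key] = val if val == "auto" else float(val)
        else:
            kwargs[key] = val
    kwargs.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**kwargs)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the pipeline; returns a summary dict of artifacts written."""
    config.validate()
    prefix = Path(config.output_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    log_lines: list[str] = [
        f"causalmix {__version__}",
        f"input = {config.input}",
        f"seed = {config.seed}",
        f"alpha = {config.alpha}",
        f"nonparanormal = {config.nonparanormal}",
    ]

    def fail(stage: str, exc: Exception):
        for p in written:
            if p.exists():
                p.rename(p.with_suffix(p.suffix + ".partial"))
        raise PipelineError(stage, exc) from exc

    # -- load -----------------------------------------------------------
    try:
        ds = read_mixed_table(config.input, delimiter=config.delimiter,
                              max_levels=config.max_levels)
        if config.nonparanormal:
            ds = nonparanormal_transform(ds)
        log_lines.append(f"n = {ds.n}, p = {ds.p}")
    except Exception as exc:  # noqa: BLE001 - stage boundary
        fail("load", exc)

    # -- prefdiv (optional) ---------------------------------------------
    if config.prefdiv_target is not None:
        try:
            pd_cfg = PrefDivConfig(
                target=config.prefdiv_target,
                num_select=config.prefdiv_num_select,
                cluster=config.prefdiv_cluster,
                tau=config.prefdiv_tau,
                keep=tuple(config.prefdiv_keep),
                seed=stage_seed(config.seed, "prefdiv"),
            )
            res = prefdiv_select(ds, pd_cfg)
            cols = [n for n in ds.names
                    if n in set(res.selected) or n == config.prefdiv_target]
            ds = ds.subset(cols)
            log_lines.append(f"prefdiv: tau = {res.tau:.4g}, "
                             f"selected = {','.join(res.selected)}")
        except Exception as exc:  # noqa: BLE001
            fail("prefdiv", exc)
    else:
        log_lines.append("prefdiv: skipped")

    # -- penalties + undirected + directed -------------------------------
    try:
        result = mgm_pcstable(
            ds,
            lambdas=(config.lambda_cc, config.lambda_cd, config.lambda_dd),
            use_steps=config.use_steps,
            alpha=config.alpha,
            max_depth=config.max_depth,
            steps_kwargs={
                "gamma": config.steps_gamma,
                "N": config.steps_subsamples,
                "seed": stage_seed(config.seed, "steps"),
            } if config.use_steps else None,
        )
        lam = result.lambdas
        log_lines.append(
            f"lambdas = ({lam.lambda_cc:.6g}, {lam.lambda_cd:.6g}, "
            f"{lam.lambda_dd:.6g}) ({'steps' if config.use_steps else 'fixed'})"
        )
        log_lines.append(f"undirected edges = {result.undirected.n_edges}")
        log_lines.append(f"ci tests = {result.n_tests}")
        log_lines.append(f"cpdag edges = {result.graph.n_edges}")
    except Exception as exc:  # noqa: BLE001
        fail("steps" if config.use_steps else "mgm", exc)

    # -- export ----------------------------------------------------------
    try:
        undirected_sif = prefix.parent / (prefix.name + ".undirected.sif")
        cpdag_sif = prefix.parent / (prefix.name + ".cpdag.sif")
        cpdag_json = prefix.parent / (prefix.name + ".cpdag.json")
        log_path = prefix.parent / (prefix.name + ".log")
        write_sif(result.undirected, undirected_sif)
        written.append(undirected_sif)
        write_sif(result.graph, cpdag_sif)
        written.append(cpdag_sif)
        write_cytoscape_json(result.graph, cpdag_json)
        written.append(cpdag_json)
        log_path.write_text("".join(line + "\n" for line in log_lines))
        written.append(log_path)
    except Exception as exc:  # noqa: BLE001
        fail("export", exc)

    return {
        "artifacts": [str(p) for p in written],
        "n_edges_undirected": result.undirected.n_edges,
        "n_edges_cpdag": result.graph.n_edges,
        "lambdas": tuple(result.lambdas),
        "n_tests": result.n_tests,
    }
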