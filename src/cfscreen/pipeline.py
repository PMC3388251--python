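"""End-to-end orchestration: generate -> screen -> evaluate, with a manifest.

Everything here is thin glue over the library modules; no screening or
statistical logic lives at this level.
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

from . import __version__
from .config import RunConfig
from .evaluation import DiseaseDefinition, compare_strategies, default_strategy_set
from .population import generate_cohort, write_cohort
from .protocol import screen_cohort

__all__ = ["RunManifest", "run_pipeline"]

log = logging.getLogger("cfscreen")


@dataclass(frozen=True)
class RunManifest:
    """Everything needed to reproduce a run's data outputs byte-for-byte.

    The wall-clock field is metadata only; no data output depends on it.
    """

    version: str
    seed: int
    config: dict
    outputs: dict[str, str]
    started_utc: str
    finished_utc: str


def _config_snapshot(config: RunConfig) -> dict:
    snap = {
        "population": asdict(config.population),
        "biomarkers": {
            "log_correlation": config.biomarkers.log_correlation,
            "params": {
                f"{p.value}.{m.value}": asdict(cp)
                for (p, m), cp in sorted(
                    config.biomarkers.params.items(),
                    key=lambda kv: (kv[0][0].value, kv[0][1].value),
                )
            },
        },
        "protocol": asdict(config.protocol),
    }
    snap["population"]["strata"] = [asdict(s) for s in config.population.strata]
    return snap


def run_pipeline(
    config: RunConfig,
    out_dir,
    disease_definition: DiseaseDefinition = DiseaseDefinition.ANY_CF,
) -> RunManifest:
    """Simulate a cohort, screen it under every strategy, summarise, write.

    Writes ``cohort.tsv``, one ``results_<strategy>.tsv`` per strategy,
    ``summary.json`` and ``manifest.json`` into ``out_dir``.  Partial
    outputs are removed if any stage fails.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    started = datetime.datetime.now(datetime.timezone.utc).isoformat()
    written: list[Path] = []
    outputs: dict[str, str] = {}
    try:
        log.info("generating cohort of %d newborns", config.population.cohort_size)
        cohort = generate_cohort(config.population, config.biomarkers)
        cohort_path = out_dir / "cohort.tsv"
        write_cohort(cohort, cohort_path)
        written.append(cohort_path)
        outputs["cohort"] = cohort_path.name

        strategies = default_strategy_set(national=config.protocol)
        for label, strategy_cfg in strategies.items():
            log.info("screening under %s", label)
            results = screen_cohort(cohort, strategy_cfg)
            path = out_dir / f"results_{label}.tsv"
            results.to_csv(path, sep="\t", index=False)
            written.append(path)
            outputs[f"results_{label}"] = path.name

        log.info("summarising strategies")
        summaries = compare_strategies(
            cohort, strategies, disease_definition=disease_definition
        )
        def _jsonable(d: dict) -> dict:
            return {
                k: (None if isinstance(v, float) and v != v else v)
                for k, v in d.items()
            }

        summary_path = out_dir / "summary.json"
        summary_path.write_text(
            json.dumps(
                {k: _jsonable(v.as_dict()) for k, v in summaries.items()},
                indent=2,
                sort_keys=True,
            )
            + "\n",
            encoding="utf-8",
        )
        written.append(summary_path)
        outputs["summary"] = summary_path.name
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise

    manifest = RunManifest(
        version=__version__,
        seed=config.population.seed,
        config=_config_snapshot(config),
        outputs=outputs,
        started_utc=started,
        finished_utc=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )
    (out_dir / "manifest.json").write_text(
        json.dumps(asdict(manifest), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    return manifest
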