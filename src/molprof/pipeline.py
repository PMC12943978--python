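"""Pipeline orchestration: run the enabled analysis stages and emit a
consolidated JSON + text report.

The three stages are independent; the orchestrator only shares the display
configuration and provenance header between them.  Data outputs are
deterministic for a fixed configuration (timestamps are confined to logs),
so re-running an identical configuration yields byte-identical files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .cdft import descriptors_from_orbitals
from .errors import InvalidInputError, MolprofError
from .io import (
    display_value,
    format_descriptor_table,
    format_fold_table,
    format_prediction,
    packaged_data_path,
    read_ct_means,
    read_ct_table,
    read_fragment_library,
    read_group_profile,
    read_orbitals,
)
from .ppfsd import predict
from .qpcr import fold_change_from_means, quantify_all, records_to_frame

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger("molprof")


class PipelineError(MolprofError, RuntimeError):
    """A stage failed; carries the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration for :func:`run_pipeline`.

    Any stage whose input path is ``None`` is skipped.  ``ct_table_path``
    (replicate-level) takes precedence over ``ct_means_path`` when both are
    given.  Display rounding applies only to the text report; the JSON
    report keeps full precision values alongside displayed ones.
    """

    out_dir: Path
    orbitals_path: Path | None = None
    profile_path: Path | None = None
    library_path: Path | None = None
    ct_table_path: Path | None = None
    ct_means_path: Path | None = None
    reference_gene: str = "GAPDH"
    control_label: str = "control"
    treated_label: str = "treated"
    display_digits: int = 3
    display_mode: str = "round"
    fold_digits: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.display_digits < 0 or self.fold_digits < 0:
            raise InvalidInputError("rounding digits must be >= 0")
        if self.display_mode not in ("round", "truncate"):
            raise InvalidInputError(f"unknown display mode {self.display_mode!r}")
        for name in (
            "orbitals_path",
            "profile_path",
            "library_path",
            "ct_table_path",
            "ct_means_path",
        ):
            value = getattr(self, name)
            if value is not None:
                path = Path(value)
                if not path.exists():
                    raise InvalidInputError(f"{name} does not exist: {path}")
                object.__setattr__(self, name, path)
        object.__setattr__(self, "out_dir", Path(self.out_dir))

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(**{k: v for k, v in payload.items()})

    @classmethod
    def packaged_example(cls, out_dir) -> "PipelineConfig":
        """Full run on the packaged worked-example fixtures."""
        return cls(
            out_dir=Path(out_dir),
            orbitals_path=packaged_data_path("b134_orbitals.json"),
            profile_path=packaged_data_path("b134_profile.json"),
            library_path=packaged_data_path("fragment_library.tsv"),
            ct_means_path=packaged_data_path("saos2_ct_means.csv"),
            control_label="Control",
            treated_label="B-134-0",
        )


def _stage_cdft(config: PipelineConfig, report: dict) -> None:
    orbitals = read_orbitals(config.orbitals_path)
    desc = descriptors_from_orbitals(orbitals)
    report["cdft"] = {
        "label": desc.label,
        "descriptors": desc.as_dict(),
        "display": {
            name: display_value(value, config.display_digits, config.display_mode)
            for name, value in desc.as_dict().items()
        },
        "text": format_descriptor_table(
            desc, config.display_digits, config.display_mode
        ),
    }


def _stage_ppfsd(config: PipelineConfig, report: dict) -> None:
    library_path = config.library_path or packaged_data_path("fragment_library.tsv")
    library = read_fragment_library(library_path)
    profile = read_group_profile(config.profile_path)
    prediction = predict(profile, library)
    report["ppfsd"] = {
        "compound_id": prediction.compound_id,
        "library": str(library_path),
        "chi_pred_magnitude": prediction.chi_pred,
        "chi_pred_signed": -prediction.chi_pred,
        "per_group_terms": prediction.per_group_terms,
        "h_term": prediction.h_term,
        "display": display_value(prediction.chi_pred, 2, config.display_mode),
        "text": format_prediction(prediction, 2, config.display_mode),
    }


def _stage_qpcr(config: PipelineConfig, report: dict) -> None:
    if config.ct_table_path is not None:
        records = read_ct_table(config.ct_table_path)
        folds = quantify_all(
            records_to_frame(records),
            config.reference_gene,
            config.control_label,
            config.treated_label,
            with_ttest=True,
        )
    else:
        means = read_ct_means(config.ct_means_path)
        ref = means[means["gene"] == config.reference_gene]
        if ref.empty:
            raise InvalidInputError(
                f"reference gene {config.reference_gene!r} not in means table"
            )
        ref_c = float(ref["mean_ct_control"].iloc[0])
        ref_t = float(ref["mean_ct_treated"].iloc[0])
        rows = []
        for _, row in means.iterrows():
            res = fold_change_from_means(
                row["gene"],
                float(row["mean_ct_control"]),
                float(row["mean_ct_treated"]),
                ref_c,
                ref_t,
            )
            rows.append(
                {
                    "gene": res.gene,
                    "dct_control": res.dct_control,
                    "dct_treated": res.dct_treated,
                    "ddct": res.ddct,
                    "fold": res.fold,
                }
            )
        import pandas as pd

        folds = pd.DataFrame(rows)
    folds = folds.assign(
        fold_2dp=[
            display_value(f, config.fold_digits, "round") for f in folds["fold"]
        ]
    )
    report["qpcr"] = {
        "reference_gene": config.reference_gene,
        "multiple_testing_correction": "none",
        "folds": folds.to_dict(orient="records"),
        "text": format_fold_table(folds, config.fold_digits, "round"),
    }


_STAGES = (
    ("cdft", "orbitals_path", _stage_cdft),
    ("ppfsd", "profile_path", _stage_ppfsd),
    ("qpcr", None, _stage_qpcr),
)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages; write JSON and text reports to ``out_dir``.

    Returns the consolidated report dict.  A stage failure raises
    :class:`PipelineError` naming the stage and cause; no partial report is
    written in that case.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "meta": {
            "version": __version__,
            "seed": config.seed,
            "display_mode": config.display_mode,
            "display_digits": config.display_digits,
        }
    }
    for stage, gate_attr, fn in _STAGES:
        if stage == "qpcr":
            enabled = (
                config.ct_table_path is not None or config.ct_means_path is not None
            )
        else:
            enabled = getattr(config, gate_attr) is not None
        if not enabled:
            logger.info("stage %s skipped (no input configured)", stage)
            continue
        logger.info("running stage %s", stage)
        try:
            fn(config, report)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineError(stage, exc) from exc

    json_path = out_dir / "report.json"
    json_path.write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    text_parts = [f"# molprof {__version__} consolidated report\n"]
    for stage in ("cdft", "ppfsd", "qpcr"):
        if stage in report:
            text_parts.append(report[stage]["text"])
    (out_dir / "report.txt").write_text("\n".join(text_parts), encoding="utf-8")
    logger.info("report written to %s", json_path)
    return report
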