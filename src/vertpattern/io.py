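"""CSV schemas and readers/writers for the pipeline stages.

All files are UTF-8 CSV with a required header.  Every file written by the
package starts with comment lines carrying the schema version, the seed and
a config hash, e.g.::

    # vertpattern schema=1 kind=morphology seed=42 config=deadbeef

Readers skip ``#`` comment lines, so the files stay round-trippable with
plain ``pandas.read_csv(..., comment="#")``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .columns import (
    ColumnError,
    Quality,
    RibObservation,
    RibState,
    Side,
    Vertebra,
    VertebralColumn,
)
from .malformations import ORGAN_SYSTEMS, Finding

SCHEMA_VERSION = 1

MORPHOLOGY_COLUMNS = [
    "subject_id", "vertebra_ordinal", "side", "rib_state", "length_ratio",
    "tp_exceeds_t1", "sacral_attached", "ls_transitional_flag", "quality",
]
FINDINGS_COLUMNS = [
    "subject_id", "term", "raw_system", "cause_context", "autopsy_available",
    *[f"avail_{s}" for s in ORGAN_SYSTEMS],
]

_STATE_ALIASES = {"tp_enlarged": RibState.TP_ENLARGED}


class SchemaError(ValueError):
    pass


def config_hash(config: object) -> str:
    """Stable short hash of any JSON-serialisable config representation."""
    try:
        payload = json.dumps(config, sort_keys=True, default=str)
    except TypeError:
        payload = repr(config)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    kind: str,
    seed: int | None = None,
    config: object = None,
    index: bool = False,
) -> Path:
    """Write a DataFrame as CSV with the standard provenance header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = f"# vertpattern schema={SCHEMA_VERSION} kind={kind}"
    if seed is not None:
        header += f" seed={seed}"
    if config is not None:
        header += f" config={config_hash(config)}"
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, index=index, lineterminator="\n")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing columns: {missing}")


def read_morphology(path: str | Path) -> list[VertebralColumn]:
    """Parse the long-format morphology CSV into per-subject columns.

    Rows with ``sacral_attached = 1`` terminate the presacral portion; the
    column quality is taken from the subject's rows (must agree).
    """
    df = read_table(path)
    return morphology_frame_to_columns(df)


def morphology_frame_to_columns(df: pd.DataFrame) -> list[VertebralColumn]:
    _require_columns(df, MORPHOLOGY_COLUMNS, "morphology")
    dup = df.duplicated(subset=["subject_id", "vertebra_ordinal", "side"])
    if dup.any():
        first = df.loc[dup, ["subject_id", "vertebra_ordinal", "side"]].iloc[0]
        raise SchemaError(
            f"duplicate subject-vertebra-side rows, first at {tuple(first)}"
        )

    columns: list[VertebralColumn] = []
    for sid, sub in df.groupby("subject_id", sort=True):
        quality = set(sub["quality"].astype(str))
        if len(quality) != 1:
            raise SchemaError(f"{sid}: inconsistent quality flags {sorted(quality)}")
        vertebrae = []
        for ordinal, rows in sub.sort_values(["vertebra_ordinal", "side"]).groupby(
            "vertebra_ordinal"
        ):
            if bool(rows["sacral_attached"].astype(int).any()):
                break
            ribs = []
            for _, row in rows.iterrows():
                ratio = row["length_ratio"]
                ratio = None if pd.isna(ratio) or ratio == "" else float(ratio)
                state = str(row["rib_state"])
                try:
                    rib_state = _STATE_ALIASES.get(state, RibState(state))
                    ribs.append(
                        RibObservation(
                            side=Side(str(row["side"])),
                            state=rib_state,
                            length_ratio=ratio,
                            tp_exceeds_t1=bool(int(row["tp_exceeds_t1"])),
                        )
                    )
                except (ValueError, ColumnError) as err:
                    raise SchemaError(
                        f"{sid} vertebra {ordinal}: {err}"
                    ) from err
            if len(ribs) != 2:
                raise SchemaError(f"{sid} vertebra {ordinal}: need rows for both sides")
            vertebrae.append(
                Vertebra(
                    ordinal=int(ordinal),
                    ribs=tuple(ribs),
                    ls_transitional=bool(rows["ls_transitional_flag"].astype(int).any()),
                )
            )
        try:
            columns.append(
                VertebralColumn(
                    subject_id=str(sid),
                    vertebrae=vertebrae,
                    quality=Quality(quality.pop()),
                )
            )
        except (ValueError, ColumnError) as err:
            raise SchemaError(f"{sid}: {err}") from err
    return columns


def read_findings(path: str | Path) -> dict[str, tuple[list[Finding], dict[str, bool]]]:
    """Parse the findings CSV into per-subject findings and availability."""
    df = read_table(path)
    return findings_frame_to_records(df)


def findings_frame_to_records(
    df: pd.DataFrame,
) -> dict[str, tuple[list[Finding], dict[str, bool]]]:
    _require_columns(df, FINDINGS_COLUMNS, "findings")
    out: dict[str, tuple[list[Finding], dict[str, bool]]] = {}
    for sid, sub in df.groupby("subject_id", sort=True):
        availability = {
            s: bool(int(sub[f"avail_{s}"].iloc[0])) for s in ORGAN_SYSTEMS
        }
        findings = []
        for _, row in sub.iterrows():
            term = row["term"]
            if pd.isna(term) or term == "":
                continue
            ctx = row["cause_context"]
            ctx_set = (
                frozenset(x for x in str(ctx).split(";") if x)
                if not pd.isna(ctx)
                else frozenset()
            )
            findings.append(
                Finding(
                    subject_id=str(sid),
                    term=str(term),
                    raw_system=str(row["raw_system"]) if not pd.isna(row["raw_system"]) else "",
                    cause_context=ctx_set,
                )
            )
        out[str(sid)] = (findings, availability)
    return out
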