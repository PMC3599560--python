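"""Structural validation for the JSON artifacts the CLI writes.

A schema here is a minimal structural contract — required keys and the
Python types of their values — checked by :func:`validate_output`.
Tests and the CLI both use it, so every emitted JSON document stays
machine-consumable.
"""

from __future__ import annotations

Number = (int, float)

SCHEMAS: dict[str, dict[str, type | tuple]] = {
    "cv_summary": {
        "algorithm": str,
        "folds": int,
        "repeats": int,
        "seed": int,
        "mean_mcc": Number,
        "sd_mcc": Number,
        "mean_accuracy": Number,
        "sd_accuracy": Number,
        "runs": list,
    },
    "model": {
        "algorithm": str,
        "class_priors": list,
    },
    "adaptive_result": {
        "best_apc": dict,
        "best_mean_mcc": Number,
        "runs": list,
    },
    "config_echo": {
        "command": str,
        "arguments": dict,
    },
}


class SchemaError(ValueError):
    pass


def validate_output(kind: str, obj: dict) -> None:
    """Raise :class:`SchemaError` unless obj has the kind's required keys."""
    try:
        schema = SCHEMAS[kind]
    except KeyError:
        raise SchemaError(f"unknown schema kind {kind!r}") from None
    if not isinstance(obj, dict):
        raise SchemaError(f"{kind}: expected a JSON object, got {type(obj).__name__}")
    for key, typ in schema.items():
        if key not in obj:
            raise SchemaError(f"{kind}: missing required key {key!r}")
        if not isinstance(obj[key], typ):
            raise SchemaError(
                f"{kind}: key {key!r} has type {type(obj[key]).__name__}"
            )
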