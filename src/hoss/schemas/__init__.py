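"""JSON schema validation for the hoss-exp-1 and hoss-config-1 dialects."""

from __future__ import annotations

import json
from importlib import resources
from functools import lru_cache

import jsonschema

__all__ = ["validate_experiment", "validate_config", "SchemaError"]


class SchemaError(ValueError):
    """A document violates its JSON schema; the message names the field."""


@lru_cache(maxsize=None)
def _schema(name: str) -> dict:
    with resources.files(__package__).joinpath(f"{name}.json").open() as fh:
        return json.load(fh)


def _validate(doc: dict, name: str) -> None:
    validator = jsonschema.Draft202012Validator(_schema(name))
    errors = sorted(validator.iter_errors(doc), key=lambda e: list(e.absolute_path))
    if errors:
        e = errors[0]
        where = "/".join(str(p) for p in e.absolute_path) or "<root>"
        raise SchemaError(f"{name} schema violation at {where!r}: {e.message}")


def validate_experiment(doc: dict) -> None:
    _validate(doc, "experiment")


def validate_config(doc: dict) -> None:
    _validate(doc, "config")
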