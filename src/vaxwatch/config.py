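"""YAML configuration loading.

One YAML file can configure the whole pipeline::

    filter:
      date_start: 2020-12-08
      date_end: 2021-04-30
      stages:
        - name: covid
          match_mode: word_boundary
          terms: [covid, coronavirus, sars-cov-2]
        - name: vaccine
          terms: [vaccine, jab, astrazeneca, pfizer, moderna]
    aefi_lexicon:
      headache: [headache, migraine]
      clots: [clot, blood clot, thrombosis]
    ensemble:
      weight_lexA: 0.45
      weight_lexB: 0.55
      positive_threshold: 0.05

Omitted sections fall back to the package defaults.
"""

from __future__ import annotations

from datetime import date
from pathlib import Path

import yaml

from .filtering import FilterSpec, FilterStage, default_filter_spec, DEFAULT_DATE_START, DEFAULT_DATE_END
from .mentions import AEFILexicon
from .sentiment import EnsembleConfig


def _as_date(v, default: date) -> date:
    if v is None:
        return default
    if isinstance(v, date):
        return v
    return date.fromisoformat(str(v))


def load_config(path) -> dict:
    """Parse a pipeline YAML config into typed objects.

    Returns a dict with keys ``filter_spec`` (:class:`FilterSpec`),
    ``aefi_lexicon`` (:class:`AEFILexicon`) and ``ensemble``
    (:class:`EnsembleConfig`).
    """
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    return parse_config(raw)


def parse_config(raw: dict) -> dict:
    fsec = raw.get("filter") or {}
    if "stages" in fsec:
        stages = tuple(
            FilterStage(
                name=s["name"],
                terms=tuple(s["terms"]),
                match_mode=s.get("match_mode", "word_boundary"),
            )
            for s in fsec["stages"]
        )
        spec = FilterSpec(
            stages=stages,
            date_start=_as_date(fsec.get("date_start"), DEFAULT_DATE_START),
            date_end=_as_date(fsec.get("date_end"), DEFAULT_DATE_END),
        )
    else:
        spec = FilterSpec(
            stages=default_filter_spec().stages,
            date_start=_as_date(fsec.get("date_start"), DEFAULT_DATE_START),
            date_end=_as_date(fsec.get("date_end"), DEFAULT_DATE_END),
        )
    lsec = raw.get("aefi_lexicon")
    lexicon = AEFILexicon({k: tuple(v) for k, v in lsec.items()}) if lsec else AEFILexicon.default()
    esec = raw.get("ensemble") or {}
    ensemble = EnsembleConfig(
        weight_lexA=float(esec.get("weight_lexA", 0.45)),
        weight_lexB=float(esec.get("weight_lexB", 0.55)),
        positive_threshold=float(esec.get("positive_threshold", 0.05)),
    )
    return {"filter_spec": spec, "aefi_lexicon": lexicon, "ensemble": ensemble}


def default_config() -> dict:
    return parse_config({})
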