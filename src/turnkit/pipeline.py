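"""End-to-end orchestration: featurize → expand context → predict →
report, driven by a small configuration mapping.

Every run writes a log recording the configuration hash, seed and
package versions, so outputs are traceable.  Missing inputs are
enumerated before any work starts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import sys
import numpy as np

from . import __version__
from .crf import load_model, predict
from .features import DEFAULT_OFFSETS, assemble_features, expand_context
from .io import QueryResult, read_fasta, read_plain_string, write_report, \
    write_report_tsv
from .profiles import read_profile_tsv, read_psiblast_pssm

logger = logging.getLogger("turnkit")

REQUIRED_KEYS = ("fasta", "pssm", "spssm", "pss", "ssprofile", "sspred",
                 "model", "out_prefix")
OPTIONAL_KEYS = ("threshold", "seed", "report_width")


class ConfigError(ValueError):
    pass


def validate_config(config: dict) -> dict:
    unknown = [k for k in config if k not in REQUIRED_KEYS + OPTIONAL_KEYS]
    if unknown:
        raise ConfigError(f"unknown config keys: {', '.join(sorted(unknown))}")
    missing = [k for k in REQUIRED_KEYS if k not in config]
    if missing:
        raise ConfigError(f"missing config keys: {', '.join(missing)}")
    absent = [config[k] for k in ("fasta", "pssm", "spssm", "pss",
                                  "ssprofile", "sspred", "model")
              if not os.path.exists(config[k])]
    if absent:
        raise ConfigError("missing input files: " + ", ".join(absent))
    cfg = dict(config)
    cfg.setdefault("threshold", 0.5)
    cfg.setdefault("seed", 0)
    cfg.setdefault("report_width", 60)
    return cfg


def run_pipeline(config: dict) -> dict:
    """Run prediction for one query and write report + TSV + log files.

    Returns a dict of the written artifact paths.
    """
    cfg = validate_config(config)
    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]

    records = read_fasta(cfg["fasta"])
    if len(records) != 1:
        raise ConfigError("pipeline expects exactly one FASTA record")
    query_id, sequence = records[0]

    pssm = read_psiblast_pssm(cfg["pssm"])
    spssm = read_profile_tsv(cfg["spssm"])
    pss = read_plain_string(cfg["pss"])
    ssprofile = read_profile_tsv(cfg["ssprofile"])
    sspred = read_plain_string(cfg["sspred"])
    model = load_model(cfg["model"])

    table = assemble_features(pssm, spssm, pss, ssprofile, sspred)
    if table.length != len(sequence):
        raise ConfigError(
            f"feature length {table.length} != sequence length {len(sequence)}"
        )
    expanded = expand_context(table, DEFAULT_OFFSETS)
    result = predict(model, expanded, threshold=float(cfg["threshold"]))

    qr = QueryResult(query_id=query_id, sequence=sequence,
                     turn_labels=result.labels,
                     turn_probability=result.turn_probability,
                     pss=pss, sspred=sspred)
    prefix = cfg["out_prefix"]
    paths = {
        "report": prefix + ".report.txt",
        "tsv": prefix + ".report.tsv",
        "log": prefix + ".log",
    }
    write_report([qr], paths["report"], width=int(cfg["report_width"]))
    write_report_tsv([qr], paths["tsv"])
    with open(paths["log"], "w") as fh:
        fh.write(json.dumps({
            "config_hash": cfg_hash,
            "seed": cfg["seed"],
            "threshold": cfg["threshold"],
            "turnkit_version": __version__,
            "python_version": sys.version.split()[0],
            "numpy_version": np.__version__,
            "n_turn_residues": int(result.labels.sum()),
            "query_length": len(sequence),
        }, indent=1) + "\n")
    logger.info("pipeline finished for %s (threshold %s, config %s)",
                query_id, cfg["threshold"], cfg_hash)
    return paths
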