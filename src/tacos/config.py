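"""YAML configuration for the command-line interface.

The YAML file mirrors the library's configuration surface in nested
sections; every key is optional and falls back to the library default:

.. code-block:: yaml

    model: {h: 50}
    graph: {k: 6, fallback: knn}
    loss: {tau: 0.5, alpha: 0.1, beta: 1.0, theta: 1.0,
           gamma_k0: 200, gamma_max: 1.0, pair_subsample: 50000}
    augment: {p_attr_1: 0.3, p_attr_2: 0.4, p_edge_1: 0.9, p_edge_2: 0.9,
              edge_keep_floor: 0.0}
    train: {lr: 0.001, epochs: 2000, stage1_epochs: 200, mnn_refresh: 25,
            k_mnn: 5, leiden_resolution: 1.0, seed: 0}
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .alignment import IntegrationConfig

_SECTION_KEYS = {
    "model": {"h": "h"},
    "graph": {"k": "graph_k"},
    "loss": {
        "tau": "tau",
        "alpha": "alpha",
        "beta": "beta",
        "theta": "theta",
        "gamma_k0": "gamma_k0",
        "gamma_max": "gamma_max",
        "pair_subsample": "pair_subsample",
        "pair_subsample_threshold": "pair_subsample_threshold",
    },
    "augment": {
        "p_attr_1": "p_attr_1",
        "p_attr_2": "p_attr_2",
        "p_edge_1": "p_edge_1",
        "p_edge_2": "p_edge_2",
        "edge_keep_floor": "edge_keep_floor",
        "stage1_p_edge_drop": "stage1_p_edge_drop",
    },
    "train": {
        "lr": "lr",
        "epochs": "epochs",
        "stage1_epochs": "stage1_epochs",
        "mnn_refresh": "mnn_refresh",
        "resample_negatives": "resample_negatives",
        "k_mnn": "k_mnn",
        "leiden_resolution": "leiden_resolution",
        "seed": "seed",
        "dtype": "dtype",
    },
}


def integration_config_from_dict(raw: dict) -> IntegrationConfig:
    kwargs = {}
    for section, mapping in _SECTION_KEYS.items():
        for key, value in (raw.get(section) or {}).items():
            if key in mapping:
                kwargs[mapping[key]] = value
    return IntegrationConfig(**kwargs)


def load_config(path) -> IntegrationConfig:
    """Read a YAML config file into an :class:`IntegrationConfig`."""
    with open(Path(path)) as fh:
        raw = yaml.safe_load(fh) or {}
    return integration_config_from_dict(raw)
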