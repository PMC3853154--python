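"""JSON (de)serialization of fitted models.

The model file is a versioned structured text document holding the
objective, a configuration echo, the PH-initializer coefficients, every
stage as (rho, nested tree record), the CV curve and the training log.
Floats round-trip exactly (shortest-repr JSON encoding), so a saved and
reloaded model predicts bit-identically.  The ``created`` timestamp is the
only field expected to differ between otherwise identical runs.
"""

from __future__ import annotations

import json
import os
import tempfile
from datetime import datetime, timezone

import numpy as np

from .boosting import SurvivalGradientBoosting
from .coxph import CoxPH

SCHEMA_VERSION = 1

__all__ = ["model_to_dict", "model_from_dict", "save_model", "load_model", "atomic_write_text"]


def model_to_dict(model: SurvivalGradientBoosting) -> dict:
    if not hasattr(model, "stages_"):
        raise RuntimeError("model is not fitted")
    init = None
    if model.init_model_ is not None:
        init = {
            "coef": model.init_model_.coef_.tolist(),
            "converged": bool(model.init_model_.converged_),
        }
    return {
        "schema_version": SCHEMA_VERSION,
        "created": datetime.now(timezone.utc).isoformat(),
        "objective": model.objective,
        "params": model.get_params(),
        "learning_rate": model.learning_rate_,
        "n_features": model.n_features_in_,
        "init": init,
        "stages": [{"rho": rho, "tree": tree.to_dict()} for rho, tree in model.stages_],
        "selected_stages": int(model.selected_stages_),
        "cv_curve": None if model.cv_curve_ is None else model.cv_curve_.tolist(),
        "training_log": model.training_log_.tolist(),
    }


def model_from_dict(doc: dict) -> SurvivalGradientBoosting:
    from .tree import RegressionTree

    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema {doc.get('schema_version')!r}")
    model = SurvivalGradientBoosting(**doc["params"])
    model.learning_rate_ = float(doc["learning_rate"])
    model.n_features_in_ = int(doc["n_features"])
    if doc["init"] is None:
        model.init_model_ = None
    else:
        cox = CoxPH()
        cox.coef_ = np.asarray(doc["init"]["coef"], dtype=float)
        cox.converged_ = bool(doc["init"]["converged"])
        cox.n_features_in_ = model.n_features_in_
        model.init_model_ = cox
    model.stages_ = [
        (float(s["rho"]), RegressionTree.from_dict(s["tree"])) for s in doc["stages"]
    ]
    model.selected_stages_ = int(doc["selected_stages"])
    model.cv_curve_ = (
        None if doc["cv_curve"] is None else np.asarray(doc["cv_curve"], dtype=float)
    )
    model.training_log_ = np.asarray(doc["training_log"], dtype=float)
    return model


def atomic_write_text(path, text: str):
    """Write via a temp file in the destination directory, then rename."""
    directory = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=directory, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def save_model(model: SurvivalGradientBoosting, path):
    atomic_write_text(path, json.dumps(model_to_dict(model), indent=1))


def load_model(path) -> SurvivalGradientBoosting:
    with open(path) as fh:
        return model_from_dict(json.load(fh))
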