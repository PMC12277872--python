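"""The four published GA-MLR activity models, frozen at printed precision.

Model 1 predicts pKi against AChE, model 2 pKi against BChE, model 3 pIC50
against MAO-A and model 4 pIC50 against MAO-B, each as a small linear
combination of typed atom-pair descriptors. Coefficients are stored exactly
as printed (3 decimals); nothing is refit. Models 3 and 4 contain
center-of-mass radial descriptors and therefore need 3D coordinates when
predicting directly from a structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

from .descriptors import compute_descriptor_matrix, parse_descriptor_name
from .molgraph import parse_structure

MODEL_IDS = (1, 2, 3, 4)


class PredictionError(ValueError):
    pass


@dataclass(frozen=True)
class PublishedModel:
    model_id: int
    response: str
    terms: tuple[tuple[str, float], ...]  # (descriptor name, coefficient)
    intercept: float

    @property
    def descriptor_names(self) -> list[str]:
        return [name for name, _ in self.terms]

    def evaluate(self, descriptor_values: Mapping[str, float]) -> float:
        total = self.intercept
        for name, coeff in self.terms:
            if name not in descriptor_values:
                raise PredictionError(
                    f"model {self.model_id} needs descriptor {name!r}; "
                    f"got {sorted(descriptor_values)}"
                )
            total += coeff * float(descriptor_values[name])
        return total


def load_published_models() -> dict[int, PublishedModel]:
    """Load the versioned model resource; validates every descriptor name."""
    with resources.files("thioqsar.data").joinpath("published_models.json").open() as fh:
        payload = json.load(fh)
    models = {}
    for entry in payload["models"]:
        terms = tuple((name, float(c)) for name, c in entry["terms"])
        for name, _ in terms:
            parse_descriptor_name(name)  # raises on grammar violation
        models[entry["model_id"]] = PublishedModel(
            model_id=entry["model_id"],
            response=entry["response"],
            terms=terms,
            intercept=float(entry["intercept"]),
        )
    return models


_MODELS: dict[int, PublishedModel] | None = None


def get_model(model_id: int) -> PublishedModel:
    global _MODELS
    if _MODELS is None:
        _MODELS = load_published_models()
    if model_id not in _MODELS:
        raise PredictionError(f"unknown model id {model_id}; valid: {MODEL_IDS}")
    return _MODELS[model_id]


def predict(model_id: int, descriptor_values: Mapping[str, float]) -> float:
    """Evaluate a published model on named descriptor values."""
    return get_model(model_id).evaluate(descriptor_values)


def predict_from_structure(
    smiles: str, model_id: int, seed: int = 42, id: str = ""
) -> dict:
    """Compute the model's descriptors from a structure, then predict.

    The seed governs 3D embedding for models with center-of-mass radial
    descriptors; deterministic per seed.
    """
    model = get_model(model_id)
    g = parse_structure(smiles, id=id or smiles)
    matrix = compute_descriptor_matrix([g], model.descriptor_names, seed=seed)
    values = matrix.row(g.name)
    return {
        "compound_id": g.name,
        "model_id": model_id,
        "response": model.response,
        "descriptor_values": values,
        "predicted": model.evaluate(values),
    }
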