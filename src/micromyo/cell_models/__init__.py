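"""Ionic membrane models and the explicit-Euler reaction substep."""

from .base import CellStateArray, IonicModelSpec, ode_substep_euler
from .bondarenko import bdk_model
from .twovar import test_model

_REGISTRY = {"bdk": bdk_model, "test": test_model}


def get_model(name: str) -> IonicModelSpec:
    """Look up a model by registry name ("bdk" or "test")."""
    try:
        return _REGISTRY[name]()
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; available: {sorted(_REGISTRY)}"
        ) from None


def available_models() -> list[str]:
    return sorted(_REGISTRY)


__all__ = [
    "CellStateArray",
    "IonicModelSpec",
    "ode_substep_euler",
    "bdk_model",
    "test_model",
    "get_model",
    "available_models",
]
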