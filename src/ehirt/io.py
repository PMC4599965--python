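"""Plain-CSV interchange for banks, samples, responses, and fit output.

Formats:
    item bank        ``item,a,b`` (one row per item)
    ability sample   ``id,z``
    response matrix  one row per testee, k binary columns (optional ``id``)
    fit items        ``item,a_hat,b_hat``
    latent grid      ``point,weight``
    initial values   ``item,a0,b0`` and ``point,w0``
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .estimation import FitResult, LatentGrid
from .simulate import AbilitySample, AbilitySpec, ItemBank, ResponseMatrix

__all__ = [
    "write_item_bank", "read_item_bank",
    "write_abilities", "read_abilities",
    "write_responses", "read_responses",
    "write_fit", "read_grid",
]


def write_item_bank(bank: ItemBank, path) -> None:
    pd.DataFrame({"item": bank.item_id, "a": bank.a, "b": bank.b}).to_csv(
        path, index=False
    )


def read_item_bank(path) -> ItemBank:
    df = pd.read_csv(path)
    return ItemBank(a=df["a"].to_numpy(), b=df["b"].to_numpy(),
                    item_id=df["item"].to_numpy())


def write_abilities(sample: AbilitySample, path) -> None:
    pd.DataFrame({"id": np.arange(1, sample.n + 1), "z": sample.z}).to_csv(
        path, index=False
    )


def read_abilities(path, spec: AbilitySpec | None = None) -> AbilitySample:
    df = pd.read_csv(path)
    return AbilitySample(z=df["z"].to_numpy(), spec=spec or AbilitySpec("normal"))


def write_responses(responses: ResponseMatrix, path, with_id: bool = True) -> None:
    df = pd.DataFrame(
        responses.x, columns=[f"item{i + 1}" for i in range(responses.k)]
    )
    if with_id:
        df.insert(0, "id", np.arange(1, responses.n + 1))
    df.to_csv(path, index=False)


def read_responses(path) -> ResponseMatrix:
    df = pd.read_csv(path)
    if "id" in df.columns:
        df = df.drop(columns="id")
    return ResponseMatrix(x=df.to_numpy())


def write_fit(result: FitResult, stem) -> None:
    """Write ``<stem>_items.csv``, ``<stem>_grid.csv`` and a key-value
    ``<stem>_meta.txt`` with convergence information."""
    stem = Path(stem)
    k = result.a_hat.size
    pd.DataFrame(
        {"item": np.arange(1, k + 1), "a_hat": result.a_hat, "b_hat": result.b_hat}
    ).to_csv(stem.with_name(stem.name + "_items.csv"), index=False)
    pd.DataFrame(
        {"point": result.grid.points, "weight": result.grid.weights}
    ).to_csv(stem.with_name(stem.name + "_grid.csv"), index=False)
    meta = {
        "n_cycles": result.n_cycles,
        "converged": result.converged,
        "final_change": result.final_change,
        "loglik": float(result.loglik_trace[-1]),
    }
    stem.with_name(stem.name + "_meta.txt").write_text(
        "".join(f"{k_}={v}\n" for k_, v in meta.items())
    )


def read_grid(path) -> LatentGrid:
    df = pd.read_csv(path)
    return LatentGrid(df["point"].to_numpy(), df["weight"].to_numpy())
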