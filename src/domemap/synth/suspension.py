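"""Paired tissue/blood suspension-cytometry event tables.

Emulates paired GALT and PBMC B-cell samples from the same donors: per donor
and compartment, subset mixing fractions are drawn around the configured
compartment means (Dirichlet), events are allocated multinomially, and marker
intensities come from the shared subset phenotype model. The tissue defaults
carry elevated DN2/3, GC and PB/PC fractions relative to blood.

Event tables hold arcsinh-transformed intensities (cofactor 5), matching how
suspension cytometry data enter the analysis stage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..stats import arcsinh_transform
from .config import SimConfig, rng_for
from .phenotypes import default_suspension_model


def simulate_suspension_pair(
    config: SimConfig,
    n_donors: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate paired GALT/PBMC event tables for ``n_donors`` donors.

    Returns ``(events, truth)``: ``events`` has one row per event with
    ``sample_id``, ``donor``, ``compartment`` and one column per marker
    (transformed scale); ``truth`` records each event's true subset and the
    donor-level realised mixing fractions are recoverable from it.
    """
    sus = config.suspension
    model = default_suspension_model()
    for name, props in (("galt", sus.galt_proportions),
                        ("pbmc", sus.pbmc_proportions)):
        total = sum(props.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"{name} proportions sum to {total}, not 1")
        if set(props) != set(sus.galt_proportions):
            raise ValueError("GALT and PBMC must list the same subsets")

    frames: list[pd.DataFrame] = []
    truths: list[pd.DataFrame] = []
    subsets = list(sus.galt_proportions)
    for donor in range(n_donors):
        for compartment, props in (("GALT", sus.galt_proportions),
                                   ("PBMC", sus.pbmc_proportions)):
            rng = rng_for(config.seed, f"suspension/{donor}/{compartment}")
            alpha = sus.donor_concentration * np.array(
                [props[s] for s in subsets])
            realised = rng.dirichlet(alpha)
            counts = rng.multinomial(sus.n_events_per_sample, realised)
            raw_blocks = []
            labels = []
            for subset, k in zip(subsets, counts):
                if k == 0:
                    continue
                raw_blocks.append(model.sample_raw(subset, int(k), rng))
                labels.extend([subset] * int(k))
            raw = np.vstack(raw_blocks) if raw_blocks else np.empty(
                (0, len(model.markers)))
            order = rng.permutation(len(labels))
            transformed = arcsinh_transform(raw[order])
            frame = pd.DataFrame(transformed, columns=list(model.markers))
            frame.insert(0, "compartment", compartment)
            frame.insert(0, "donor", f"D{donor}")
            frame.insert(0, "sample_id", f"D{donor}_{compartment}")
            frames.append(frame)
            truths.append(pd.DataFrame({
                "sample_id": f"D{donor}_{compartment}",
                "donor": f"D{donor}",
                "compartment": compartment,
                "true_subset": np.array(labels)[order],
            }))

    if not frames:
        cols = ["sample_id", "donor", "compartment", *model.markers]
        return (pd.DataFrame(columns=cols),
                pd.DataFrame(columns=["sample_id", "donor", "compartment",
                                      "true_subset"]))
    events = pd.concat(frames, ignore_index=True)
    truth = pd.concat(truths, ignore_index=True)
    events.index.name = "event_id"
    truth.index.name = "event_id"
    return events, truth
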