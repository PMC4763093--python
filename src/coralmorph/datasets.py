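"""Bundled example data.

``reference_colonies`` loads the raw surface-area and volume measurements
of ten Indo-Pacific coral colonies spanning five growth forms, digitised
by underwater and dry multi-image photogrammetry.  These are the
non-derived measurements; the full derived suite is recomputed from them
by :func:`coralmorph.metrics.report_table`.  Empty cells are volumes of
colonies whose models never reconstructed as coherent solids.
"""

from __future__ import annotations

from importlib import resources

from .metrics import ColonyMeasurements, read_measurements_csv

__all__ = ["reference_colonies", "reference_colonies_path"]


def reference_colonies_path():
    """Path to the bundled colony-measurements CSV."""
    return resources.files("coralmorph") / "data" / "reference_colonies.csv"


def reference_colonies() -> list[ColonyMeasurements]:
    """The ten-colony reference measurement set."""
    with resources.as_file(reference_colonies_path()) as p:
        return read_measurements_csv(p)
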