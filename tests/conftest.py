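import numpy as np
import pytest
from shapely.geometry import box

from beescape.grid import (
    FieldRecord,
    FieldRegistry,
    LandscapeGrid,
    LULCMap,
    default_class_table,
)


def make_grid(n_rows=20, n_cols=20, resolution=30.0) -> LandscapeGrid:
    return LandscapeGrid(
        origin_x=0.0,
        origin_y=n_rows * resolution,
        n_rows=n_rows,
        n_cols=n_cols,
        resolution=resolution,
    )


def make_lulc(codes, buffer_m=0.0) -> LULCMap:
    codes = np.asarray(codes, dtype=np.int32)
    grid = make_grid(*codes.shape)
    return LULCMap(grid, codes, default_class_table(), analysis_buffer_m=buffer_m)


def make_field(field_id, minx, miny, maxx, maxy, history=None) -> FieldRecord:
    poly = box(minx, miny, maxx, maxy)
    return FieldRecord(
        field_id=field_id,
        polygon=poly,
        area_ha=poly.area / 10_000.0,
        history=history or {},
    )


def history(years, cultivated, crop="corn"):
    """Uniform history helper: same status/crop for every listed year."""
    return {y: (cultivated, crop if cultivated else "") for y in years}


@pytest.fixture(scope="session")
def default_bundle():
    """One shared 6x6-km synthetic landscape (seed 1, study-default config)."""
    from beescape.synth import SynthConfig, generate_landscape

    return generate_landscape(SynthConfig(seed=1))


@pytest.fixture(scope="session")
def default_run():
    """One shared full five-scenario pipeline run on the default landscape."""
    import warnings

    from beescape.pipeline import RunConfig, run_pipeline

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(RunConfig(seed=1))
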