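import numpy as np
import pandas as pd
import pytest

from reefaes import annotation, imaging, synthgen


@pytest.fixture(scope="session")
def quadrat_batch():
    """30 small quadrats (10 per habitat) with masks, truths and features."""
    rng = np.random.default_rng(12345)
    images, masks, truths, rows = {}, {}, {}, []
    for hab in ("healthy", "restored", "degraded"):
        preset = synthgen.HABITAT_PRESETS[hab]
        for i in range(10):
            img, mask, truth = synthgen.generate_quadrat(
                preset, seed=int(rng.integers(2**31)), side=96,
                image_id=f"{hab}-{i}",
            )
            images[img.image_id] = img
            masks[img.image_id] = mask
            truths[img.image_id] = truth
            tp = imaging.colour_thumbprint(img.pixels)
            fv = annotation.assemble_features(
                img, tp, imaging.group_shares(tp), mask,
                seed=int(rng.integers(2**31)),
            )
            rows.append(fv.as_dict())
    features = pd.DataFrame(rows).set_index("image_id")
    return {
        "images": images,
        "masks": masks,
        "truths": truths,
        "features": features,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
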