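import numpy as np
import pytest

from keyfg.coco import Annotation, Category, DetectionDataset, ImageInfo


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_dataset():
    """2 images, 3 boxes, in-memory pixels: plain colour fields with
    distinctly coloured boxes."""
    ds = DetectionDataset(categories=[Category(id=1, name="pest")])
    r = np.random.default_rng(0)
    for image_id, n_boxes in ((1, 2), (2, 1)):
        img = np.full((100, 100, 3), 30, dtype=np.uint8)
        img += r.integers(0, 5, size=img.shape, dtype=np.uint8)
        ds.images.append(ImageInfo(id=image_id, width=100, height=100,
                                   file_name=f"img{image_id}.png"))
        for b in range(n_boxes):
            x, y = 10 + 40 * b, 20 + 30 * b
            img[y:y + 10, x:x + 10] = 200
            ds.annotations.append(
                Annotation(id=len(ds.annotations) + 1, image_id=image_id,
                           bbox=(x, y, 10, 10), category_id=1)
            )
        ds.pixels[image_id] = img
    ds.validate()
    return ds
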