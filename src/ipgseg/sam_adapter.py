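"""Optional adapter to the pretrained foundation segmenter.

This backend wraps a Segment Anything checkpoint behind the same
``segment``/``embed`` contract as the oracle backend.  It needs the optional
``sam`` extra (``pip install ipgseg[sam]``) plus a downloaded checkpoint, and
prefers a GPU; the core pipeline and test suite run entirely on the oracle
backend and never import this module.
"""

from __future__ import annotations

import numpy as np

from .segmenter import FOREGROUND, FeatureField, PointPrompt, SegmentationResult


class SamSegmenter:
    """Foundation-model backend (optional extra).

    Parameters
    ----------
    checkpoint:
        Path to a Segment Anything checkpoint file.
    model_type:
        Architecture key understood by the upstream registry, e.g. ``vit_b``.
    device:
        Torch device string.
    """

    source = "foundation-model encoder"

    def __init__(self, checkpoint: str, model_type: str = "vit_b",
                 device: str = "cpu") -> None:
        try:
            import torch  # noqa: F401
            from segment_anything import SamPredictor, sam_model_registry
        except ImportError as exc:  # pragma: no cover - optional extra
            raise ImportError(
                "the foundation-segmenter backend needs the optional 'sam' "
                "extra: pip install ipgseg[sam]"
            ) from exc
        sam = sam_model_registry[model_type](checkpoint=checkpoint)
        sam.to(device)
        self._predictor = SamPredictor(sam)

    def segment(self, image3: np.ndarray, prompts: list[PointPrompt]) -> SegmentationResult:
        fg = [p for p in prompts if p.polarity == FOREGROUND]
        if not fg:
            raise ValueError("at least one foreground prompt is required")
        img = np.clip(image3, 0, 255).astype(np.uint8)
        self._predictor.set_image(img)
        coords = np.array([[p.col, p.row] for p in prompts], dtype=np.float64)
        labels = np.array([1 if p.polarity == FOREGROUND else 0 for p in prompts])
        masks, scores, logits = self._predictor.predict(
            point_coords=coords, point_labels=labels, multimask_output=False
        )
        logit = self._upsample_logits(logits[0], img.shape[:2])
        score = 1.0 / (1.0 + np.exp(-logit))
        return SegmentationResult(mask=score >= 0.5, score=score)

    def embed(self, image3: np.ndarray) -> FeatureField:
        import torch
        import torch.nn.functional as F

        img = np.clip(image3, 0, 255).astype(np.uint8)
        self._predictor.set_image(img)
        emb = self._predictor.get_image_embedding()  # (1, D, h, w)
        h, w = img.shape[:2]
        emb = F.interpolate(emb, size=(h, w), mode="bilinear", align_corners=False)
        field = emb[0].permute(1, 2, 0).cpu().numpy().astype(np.float64)
        return FeatureField(embedding=field, source=self.source)

    @staticmethod
    def _upsample_logits(logit: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
        from scipy.ndimage import zoom

        zh = shape[0] / logit.shape[0]
        zw = shape[1] / logit.shape[1]
        return zoom(logit, (zh, zw), order=1)
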