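import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def flood_fill_components(mask, connectivity8=True):
    """Independent component census: BFS flood fill, returns list of pixel sets."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    if connectivity8:
        neigh = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        neigh = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    components = []
    rows, cols = mask.shape
    for r0 in range(rows):
        for c0 in range(cols):
            if mask[r0, c0] and not seen[r0, c0]:
                stack, comp = [(r0, c0)], set()
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    comp.add((r, c))
                    for dr, dc in neigh:
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < rows and 0 <= cc < cols and mask[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            stack.append((rr, cc))
                components.append(comp)
    return components
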