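"""ROI segmentation against constructed geometry and generator ground truth."""

import numpy as np
import pytest
from skimage.draw import disk as draw_disk

from compartquant.segmentation import (ChannelImage, ROILabelMap, map2_cell_count,
                                       segment_nuclei, segment_soma, trace_neurites,
                                       whole_cell_mask)

PX = 0.3


def no_soma(shape):
    return ROILabelMap(np.zeros(shape, np.int32), "soma", PX)


def draw_line_um(img, start, angle, length_um, value=500.0, px=PX):
    n = int(length_um / px)
    for i in range(n + 1):
        r = int(round(start[0] + i * np.sin(angle)))
        c = int(round(start[1] + i * np.cos(angle)))
        img[r, c] = value
    return img


class TestNuclei:
    def test_blank_image_no_nuclei(self):
        out = segment_nuclei(ChannelImage(np.zeros((64, 64)), PX))
        assert out.n_labels == 0

    def test_five_disks_found_with_centers(self):
        img = np.zeros((300, 300))
        centers = [(40, 40), (40, 150), (150, 40), (150, 150), (250, 250)]
        for c in centers:
            rr, cc = draw_disk(c, 12, shape=img.shape)
            img[rr, cc] = 800.0
        out = segment_nuclei(ChannelImage(img, PX))
        assert out.n_labels == 5
        for c in centers:
            got = np.array(np.nonzero(out.labels == out.labels[c])).mean(axis=1)
            assert np.hypot(*(got - np.array(c))) <= 1.0

    def test_touching_disks_split_by_watershed(self):
        img = np.zeros((100, 100))
        for c in [(50, 40), (50, 58)]:  # overlap < one radius
            rr, cc = draw_disk(c, 12, shape=img.shape)
            img[rr, cc] = 800.0
        assert segment_nuclei(ChannelImage(img, PX)).n_labels == 2

    def test_area_gate_in_physical_units(self):
        img = np.zeros((100, 100))
        rr, cc = draw_disk((50, 50), 3, shape=img.shape)  # ~2.5 um2, below floor
        img[rr, cc] = 800.0
        assert segment_nuclei(ChannelImage(img, PX), min_area_um2=20).n_labels == 0


class TestSoma:
    def _cell(self, nucleus_r=12, soma_r=24):
        img = np.zeros((160, 160))
        rr, cc = draw_disk((80, 80), soma_r, shape=img.shape)
        img[rr, cc] = 600.0
        dapi = np.zeros_like(img)
        rr, cc = draw_disk((80, 80), nucleus_r, shape=img.shape)
        dapi[rr, cc] = 900.0
        return img, dapi

    def test_no_nuclei_no_somata(self):
        img, _ = self._cell()
        empty_nuclei = ROILabelMap(np.zeros(img.shape, np.int32), "nucleus", PX)
        out = segment_soma(ChannelImage(img, PX), empty_nuclei)
        assert out.n_labels == 0

    def test_soma_contains_nucleus(self):
        img, dapi = self._cell()
        nuc = segment_nuclei(ChannelImage(dapi, PX))
        soma = segment_soma(ChannelImage(img, PX), nuc)
        assert soma.n_labels == 1
        assert np.all(soma.labels[nuc.labels > 0] == nuc.labels[nuc.labels > 0])
        assert (soma.labels > 0).sum() >= (nuc.labels > 0).sum()

    def test_two_nuclei_partition_shared_blob(self):
        img = np.zeros((160, 240))
        rr, cc = draw_disk((80, 90), 30, shape=img.shape)
        img[rr, cc] = 600.0
        rr, cc = draw_disk((80, 140), 30, shape=img.shape)
        img[rr, cc] = 600.0
        dapi = np.zeros_like(img)
        for c in ((80, 90), (80, 140)):
            rr, cc = draw_disk(c, 12, shape=dapi.shape)
            dapi[rr, cc] = 900.0
        nuc = segment_nuclei(ChannelImage(dapi, PX))
        soma = segment_soma(ChannelImage(img, PX), nuc, opening_radius_um=0.0)
        assert soma.n_labels == 2
        # nearest-seed split: left half of the blob belongs to the left nucleus
        left_label = soma.labels[80, 90]
        right_label = soma.labels[80, 140]
        assert left_label != right_label
        assert soma.labels[80, 100] == left_label
        assert soma.labels[80, 130] == right_label

    def test_shape_mismatch_rejected(self):
        img, dapi = self._cell()
        nuc = segment_nuclei(ChannelImage(dapi, PX))
        with pytest.raises(ValueError, match="shape"):
            segment_soma(ChannelImage(np.zeros((10, 10)), PX), nuc)


class TestNeurites:
    def test_blank_channel_zero_length(self):
        sk = trace_neurites(ChannelImage(np.zeros((64, 64)), PX), no_soma((64, 64)))
        assert sk.total_length_um == 0.0 and sk.endpoint_count == 0

    def test_straight_line_length_and_endpoints(self):
        img = np.zeros((60, 200))
        img[30, 50:151] = 500.0  # 101 px -> 100 steps of 0.3 um
        sk = trace_neurites(ChannelImage(img, PX), no_soma(img.shape))
        assert sk.total_length_um == pytest.approx(30.0, abs=0.6)
        assert sk.endpoint_count == 2

    def test_y_tree_length_and_tips(self):
        img = np.zeros((200, 200))
        draw_line_um(img, (30, 100), np.pi / 2, 20)
        branch_point = (30 + int(20 / PX), 100)
        draw_line_um(img, branch_point, np.pi / 2 - 0.6, 10)
        draw_line_um(img, branch_point, np.pi / 2 + 0.6, 10)
        sk = trace_neurites(ChannelImage(img, PX), no_soma(img.shape))
        assert sk.total_length_um == pytest.approx(40.0, rel=0.05)
        assert sk.endpoint_count == 3

    def test_disjoint_segment_only_adds_length(self):
        img = np.zeros((100, 200))
        img[30, 20:120] = 500.0
        base = trace_neurites(ChannelImage(img, PX), no_soma(img.shape)).total_length_um
        img2 = img.copy()
        img2[70, 20:90] = 500.0
        more = trace_neurites(ChannelImage(img2, PX), no_soma(img.shape)).total_length_um
        assert more > base

    def test_scale_equivariance(self):
        img = np.zeros((60, 200))
        img[30, 50:151] = 500.0
        l1 = trace_neurites(ChannelImage(img, PX), no_soma(img.shape)).total_length_um
        l2 = trace_neurites(ChannelImage(img, 2 * PX), no_soma(img.shape)).total_length_um
        assert l2 == pytest.approx(2 * l1)


class TestWholeCell:
    def test_blank_zero_cells(self):
        wc = whole_cell_mask(ChannelImage(np.zeros((64, 64)), PX))
        assert wc.n_labels == 0

    def test_three_disjoint_cells(self):
        img = np.zeros((300, 300))
        for c in ((60, 60), (60, 220), (220, 140)):
            rr, cc = draw_disk(c, 25, shape=img.shape)
            img[rr, cc] = 600.0
        assert whole_cell_mask(ChannelImage(img, PX)).n_labels == 3

    def test_cell_without_nucleus_excluded_from_count(self):
        img = np.zeros((300, 300))
        for c in ((60, 60), (220, 220)):
            rr, cc = draw_disk(c, 25, shape=img.shape)
            img[rr, cc] = 600.0
        dapi = np.zeros_like(img)
        rr, cc = draw_disk((60, 60), 12, shape=dapi.shape)
        dapi[rr, cc] = 900.0
        wc = whole_cell_mask(ChannelImage(img, PX))
        nuc = segment_nuclei(ChannelImage(dapi, PX))
        assert wc.n_labels == 2
        assert map2_cell_count(wc, nuc) == 1


class TestPartitionInvariants:
    def test_generated_well_partition(self, default_plate):
        plate, truth = default_plate
        wid = plate.plate_map.query("role == 'sample'").well.iloc[0]
        dapi = ChannelImage(np.clip(plate.channel(wid, "dapi"), 0, None), plate.pixel_size_um)
        map2 = ChannelImage(np.clip(plate.channel(wid, "map2"), 0, None), plate.pixel_size_um)
        nuc = segment_nuclei(dapi)
        soma = segment_soma(map2, nuc)
        sk = trace_neurites(map2, soma)
        assert nuc.n_labels == len(truth.wells[wid].nuclei_centers)
        # nucleus subset of soma, per label
        assert np.all(soma.labels[nuc.labels > 0] == nuc.labels[nuc.labels > 0])
        # neurite skeleton never enters a soma
        assert not np.any(sk.mask & (soma.labels > 0))
        # recovered total length close to placed polyline length
        placed = sum(truth.wells[wid].neurite_lengths_um)
        assert sk.total_length_um == pytest.approx(placed, rel=0.12)
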