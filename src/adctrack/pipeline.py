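"""End-to-end glue: phantom (or file) inputs -> ADC map -> viable-tumor
histogram summaries -> longitudinal series."""

from __future__ import annotations

from .adc import ADCMap, fit_adc_multib, fit_adc_pair
from .longitudinal import LongitudinalSeries, TimePoint
from .phantom import PhantomOutput
from .roi import (
    HistogramSummary,
    ROIMask,
    compute_volume,
    extract_values,
    subtract_rois,
    summarize_histogram,
)


def summarize_week(
    adc_map: ADCMap, gtv: ROIMask, cystic: ROIMask | None = None
) -> tuple[HistogramSummary, float]:
    """Viable-tumor ADC summary and whole-GTV volume for one timepoint.

    ADC statistics are computed on the viable region (GTV minus
    cystic/necrotic when one is supplied); volume follows clinical practice
    and covers the entire GTV including cystic parts.
    """
    if cystic is not None and cystic.mask.any():
        viable = subtract_rois(gtv, cystic)
    else:
        viable = ROIMask(gtv.mask, "viable", gtv.voxel_spacing, name=gtv.name)
    values = extract_values(adc_map, viable)
    summary = summarize_histogram(values, volume_cm3=compute_volume(viable))
    return summary, compute_volume(gtv)


def series_from_phantom(
    output: PhantomOutput, gtv_id: str = "gtv", method: str = "pair"
) -> LongitudinalSeries:
    """Run the full measurement pipeline on a generated phantom."""
    fit = fit_adc_pair if method == "pair" else fit_adc_multib
    timepoints = []
    for wk in output.weeks:
        adc_map = fit(wk.series)
        summary, gtv_vol = summarize_week(
            adc_map, wk.masks["gtv"], wk.masks["cystic_necrotic"]
        )
        timepoints.append(
            TimePoint(
                week=wk.week,
                adc_summary=summary,
                gtv_volume_cm3=gtv_vol,
                days_from_rt_start=wk.series.days_from_rt_start,
            )
        )
    return LongitudinalSeries(gtv_id=gtv_id, timepoints=timepoints)
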