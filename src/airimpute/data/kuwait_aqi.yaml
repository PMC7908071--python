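# Kuwait Air Quality Index breakpoint grid.
# Per pollutant: ordered segments [c_low, c_high, i_low, i_high, category].
# Units: ppm for gases, ug/m3 for PM10.  Averaging window stored as
# metadata; the printed grid lists CO under a 24-h header although the
# study's concentration time for CO is 8 h, so both are recorded.
categories:
  - Good
  - Moderate
  - Unhealthy (1)
  - Unhealthy (2)
  - Very Unhealthy
  - Hazardous
pollutants:
  O3:
    units: ppm
    window_hours: 8
    segments:
      - [0.0, 0.03, 0, 50, Good]
      - [0.031, 0.06, 51, 100, Moderate]
      - [0.061, 0.092, 101, 150, Unhealthy (1)]
      - [0.093, 0.124, 151, 200, Unhealthy (2)]
      - [0.125, 0.374, 201, 300, Very Unhealthy]
      - [0.375, 0.504, 301, 500, Hazardous]
  PM10:
    units: ug/m3
    window_hours: 24
    segments:
      - [0.0, 90.0, 0, 50, Good]
      - [90.1, 350.0, 51, 100, Moderate]
      - [350.1, 431.1, 101, 150, Unhealthy (1)]
      - [431.4, 512.5, 151, 200, Unhealthy (2)]
      - [512.6, 675.0, 201, 300, Very Unhealthy]
      - [675.1, 1000.0, 301, 500, Hazardous]
  CO:
    units: ppm
    window_hours: 24
    window_hours_alt: 8
    segments:
      - [0.0, 4.0, 0, 50, Good]
      - [4.1, 8.0, 51, 100, Moderate]
      - [8.1, 11.7, 101, 150, Unhealthy (1)]
      - [11.8, 15.4, 151, 200, Unhealthy (2)]
      - [15.5, 30.4, 201, 300, Very Unhealthy]
      - [30.5, 50.4, 301, 500, Hazardous]
  SO2:
    units: ppm
    window_hours: 24
    segments:
      - [0.0, 0.03, 0, 50, Good]
      - [0.031, 0.06, 51, 100, Moderate]
      - [0.061, 0.182, 101, 150, Unhealthy (1)]
      - [0.183, 0.304, 151, 200, Unhealthy (2)]
      - [0.305, 0.604, 201, 300, Very Unhealthy]
      - [0.605, 1.004, 301, 500, Hazardous]
  NO2:
    units: ppm
    window_hours: 24
    segments:
      - [0.0, 0.03, 0, 50, Good]
      - [0.04, 0.05, 51, 100, Moderate]
      - [0.06, 0.30, 101, 150, Unhealthy (1)]
      - [0.31, 0.55, 151, 200, Unhealthy (2)]
      - [0.56, 1.04, 201, 300, Very Unhealthy]
      - [1.05, 2.04, 301, 500, Hazardous]
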