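# Synthetic approximation of the global atmospheric CO2 record:
# Ca (umol mol-1) interpolated between ice-core / Mauna Loa era anchors,
# d13C_atm (permil VPDB) following the observed Suess-effect decline.
# Replace with a measured reference table for real analyses.
year,Ca,d13C_atm
1920,303.00,-6.750
1921,303.30,-6.755
1922,303.60,-6.760
1923,303.90,-6.765
1924,304.20,-6.770
1925,304.50,-6.775
1926,304.80,-6.780
1927,305.10,-6.785
1928,305.40,-6.790
1929,305.70,-6.795
1930,306.00,-6.800
1931,306.50,-6.805
1932,307.00,-6.810
1933,307.50,-6.815
1934,308.00,-6.820
1935,308.50,-6.825
1936,309.00,-6.830
1937,309.50,-6.835
1938,310.00,-6.840
1939,310.50,-6.845
1940,311.00,-6.850
1941,311.03,-6.855
1942,311.06,-6.860
1943,311.09,-6.865
1944,311.12,-6.870
1945,311.15,-6.875
1946,311.18,-6.880
1947,311.21,-6.885
1948,311.24,-6.890
1949,311.27,-6.895
1950,311.30,-6.900
1951,311.76,-6.905
1952,312.23,-6.910
1953,312.69,-6.915
1954,313.15,-6.920
1955,313.61,-6.925
1956,314.07,-6.930
1957,314.54,-6.935
1958,315.00,-6.940
1959,315.95,-6.945
1960,316.90,-6.950
1961,317.78,-6.975
1962,318.66,-7.000
1963,319.54,-7.025
1964,320.42,-7.050
1965,321.30,-7.075
1966,322.18,-7.100
1967,323.06,-7.125
1968,323.94,-7.150
1969,324.82,-7.175
1970,325.70,-7.200
1971,327.01,-7.230
1972,328.32,-7.260
1973,329.63,-7.290
1974,330.94,-7.320
1975,332.25,-7.350
1976,333.56,-7.380
1977,334.87,-7.410
1978,336.18,-7.440
1979,337.49,-7.470
1980,338.80,-7.500
1981,340.36,-7.525
1982,341.92,-7.550
1983,343.48,-7.575
1984,345.04,-7.600
1985,346.60,-7.625
1986,348.16,-7.650
1987,349.72,-7.675
1988,351.28,-7.700
1989,352.84,-7.725
1990,354.40,-7.750
1991,355.92,-7.775
1992,357.44,-7.800
1993,358.96,-7.825
1994,360.48,-7.850
1995,362.00,-7.875
1996,363.52,-7.900
1997,365.04,-7.925
1998,366.56,-7.950
1999,368.08,-7.975
2000,369.60,-8.000
2001,371.65,-8.030
2002,373.70,-8.060
2003,375.75,-8.090
2004,377.80,-8.120
2005,379.85,-8.150
2006,381.90,-8.180
2007,383.95,-8.210
2008,386.00,-8.240
2009,388.05,-8.270
2010,390.10,-8.300
2011,392.51,-8.330
2012,394.92,-8.360
2013,397.33,-8.390
2014,399.74,-8.420
2015,402.15,-8.450
2016,404.56,-8.480
2017,406.97,-8.510
2018,409.38,-8.540
2019,411.79,-8.570
2020,414.20,-8.600
2021,416.50,-8.633
2022,418.80,-8.667
2023,421.10,-8.700
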