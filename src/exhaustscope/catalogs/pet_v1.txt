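# PET feature catalog, version 1 — 61 features computed on SUV
# families: IntensityDirect (17), IntensityHistogram (12), GLCM (21), GLRLM (11)
Mean(IntensityDirect)
Median(IntensityDirect)
Minimum(IntensityDirect)
Maximum(IntensityDirect)
Range(IntensityDirect)
Variance(IntensityDirect)
StandardDeviation(IntensityDirect)
Skewness(IntensityDirect)
Kurtosis(IntensityDirect)
Energy(IntensityDirect)
RootMeanSquare(IntensityDirect)
MeanAbsoluteDeviation(IntensityDirect)
Percentile10(IntensityDirect)
Percentile25(IntensityDirect)
Percentile75(IntensityDirect)
Percentile90(IntensityDirect)
InterquartileRange(IntensityDirect)
Mean(IntensityHistogram)
Median(IntensityHistogram)
Minimum(IntensityHistogram)
Maximum(IntensityHistogram)
Range(IntensityHistogram)
Variance(IntensityHistogram)
Skewness(IntensityHistogram)
Kurtosis(IntensityHistogram)
Entropy(IntensityHistogram)
Uniformity(IntensityHistogram)
Percentile10(IntensityHistogram)
Percentile90(IntensityHistogram)
AutoCorrelation(GLCM)
ClusterProminence(GLCM)
ClusterShade(GLCM)
ClusterTendency(GLCM)
Contrast(GLCM)
Correlation(GLCM)
DifferenceAverage(GLCM)
DifferenceEntropy(GLCM)
DifferenceVariance(GLCM)
Dissimilarity(GLCM)
Energy(GLCM)
Entropy(GLCM)
Homogeneity(GLCM)
Homogeneity2(GLCM)
InformationMeasureCorr1(GLCM)
InformationMeasureCorr2(GLCM)
InverseVariance(GLCM)
MaxProbability(GLCM)
SumAverage(GLCM)
SumEntropy(GLCM)
SumVariance(GLCM)
ShortRunEmphasis(GLRLM)
LongRunEmphasis(GLRLM)
GrayLevelNonuniformity(GLRLM)
RunLengthNonuniformity(GLRLM)
RunPercentage(GLRLM)
LowGrayLevelRunEmphasis(GLRLM)
HighGrayLevelRunEmphasis(GLRLM)
ShortRunLowGrayLevelEmphasis(GLRLM)
ShortRunHighGrayLevelEmphasis(GLRLM)
LongRunLowGrayLevelEmphasis(GLRLM)
LongRunHighGrayLevelEmphasis(GLRLM)
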