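# CT feature catalog, version 1 — 57 features on raw density
# families: Shape (10), IntensityDirect (11), IntensityHistogram (8), GLCM (18), GLRLM (10)
Volume(Shape)
SurfaceArea(Shape)
SurfaceAreaDensity(Shape)
Compactness1(Shape)
Compactness2(Shape)
Sphericity(Shape)
SphericalDisproportion(Shape)
Maximum3DDiameter(Shape)
ConvexHullVolume3D(Shape)
Solidity(Shape)
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
MeanAbsoluteDeviation(IntensityDirect)
Mean(IntensityHistogram)
Median(IntensityHistogram)
Range(IntensityHistogram)
Variance(IntensityHistogram)
Skewness(IntensityHistogram)
Kurtosis(IntensityHistogram)
Entropy(IntensityHistogram)
Uniformity(IntensityHistogram)
AutoCorrelation(GLCM)
ClusterProminence(GLCM)
ClusterShade(GLCM)
ClusterTendency(GLCM)
Contrast(GLCM)
Correlation(GLCM)
DifferenceEntropy(GLCM)
DifferenceVariance(GLCM)
Dissimilarity(GLCM)
Energy(GLCM)
Entropy(GLCM)
Homogeneity(GLCM)
Homogeneity2(GLCM)
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
ShortRunHighGrayLevelEmphasis(GLRLM)
LongRunLowGrayLevelEmphasis(GLRLM)
LongRunHighGrayLevelEmphasis(GLRLM)
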