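map,zone,metric,cls,value_pct
pixel,zone1,overall,,83.3
pixel,zone1,users,noncrop,87.7
pixel,zone1,users,crop,71.2
pixel,zone1,producers,noncrop,89.3
pixel,zone1,producers,crop,67.9
pixel,zone2,overall,,86.5
pixel,zone2,users,noncrop,91.7
pixel,zone2,users,crop,64.8
pixel,zone2,producers,noncrop,91.5
pixel,zone2,producers,crop,65.3
pixel,zone3,overall,,93.6
pixel,zone3,users,noncrop,94.9
pixel,zone3,users,crop,71.4
pixel,zone3,producers,noncrop,98.2
pixel,zone3,producers,crop,45.6
pixel,zone4,overall,,89.1
pixel,zone4,users,noncrop,93.8
pixel,zone4,users,crop,59.8
pixel,zone4,producers,noncrop,93.4
pixel,zone4,producers,crop,61.4
pixel,ghana,overall,,88.0
pixel,ghana,users,noncrop,92.0
pixel,ghana,users,crop,67.3
pixel,ghana,producers,noncrop,93.6
pixel,ghana,producers,crop,61.7
segmentation,zone1,overall,,81.4
segmentation,zone1,users,noncrop,93.2
segmentation,zone1,users,crop,62.3
segmentation,zone1,producers,noncrop,80.0
segmentation,zone1,producers,crop,84.9
segmentation,zone2,overall,,85.2
segmentation,zone2,users,noncrop,95.0
segmentation,zone2,users,crop,56.9
segmentation,zone2,producers,crop,80.1
segmentation,zone3,overall,,92.6
segmentation,zone3,users,noncrop,96.6
segmentation,zone3,users,crop,58.3
segmentation,zone3,producers,noncrop,95.2
segmentation,zone3,producers,crop,66.7
segmentation,zone4,overall,,86.1
segmentation,zone4,users,noncrop,95.7
segmentation,zone4,users,crop,50.9
segmentation,zone4,producers,noncrop,87.8
segmentation,zone4,producers,crop,76.0
segmentation,ghana,overall,,86.7
segmentation,ghana,users,noncrop,95.3
segmentation,ghana,users,crop,58.2
segmentation,ghana,producers,noncrop,88.3
segmentation,ghana,producers,crop,78.9
segmentation,ghana,adjusted_proportion,crop,17.1
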