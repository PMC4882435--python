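construct,receptor,pct,se,ci_excludes_100
L195A,AM1,91.2,2.08,0
L195A,AM2,81.4,25.9,0
T196A,AM1,94.9,17.8,0
T196A,AM2,90.5,20.1,0
A197L,AM1,111.4,7.28,0
A197L,AM2,85.9,21.2,0
V198A,AM1,105.8,14.1,0
V198A,AM2,84.3,19.0,0
A199L,AM1,99.8,7.56,0
A199L,AM2,136.7,76.6,0
N200A,AM1,100.1,6.69,0
N200A,AM2,48.4,8.62,0
N201A,AM1,81.9,15.9,0
N201A,AM2,38.9,13.4,0
Q202A,AM1,94.8,1.92,0
Q202A,AM2,83.2,10.2,0
A203L,AM1,95.5,9.67,0
A203L,AM2,72.1,18.4,0
L204A,AM1,98.3,2.83,0
L204A,AM2,114.0,15.8,0
V205A,AM1,117.3,6.49,0
V205A,AM2,88.7,13.1,0
A206L,AM1,92.9,8.45,0
A206L,AM2,91.4,13.1,0
T207A,AM1,99.9,1.52,0
T207A,AM2,82.2,15.5,0
N208A,AM1,98.6,1.02,0
N208A,AM2,111.5,18.4,0
P209A,AM1,100.3,5.96,0
P209A,AM2,118.6,34.5,0
V210A,AM1,100.4,5.63,0
V210A,AM2,88.2,15.0,0
S211A,AM1,97.5,3.73,0
S211A,AM2,95.4,18.7,0
C212A,AM1,119.0,25.1,0
C212A,AM2,93.6,22.1,0
K213A,AM1,131.3,33.1,0
K213A,AM2,84.3,21.3,0
V214A,AM1,87.5,9.71,0
V214A,AM2,86.6,17.9,0
S215A,AM1,86.2,10.7,0
S215A,AM2,84.5,17.3,0
Q216A,AM1,95.7,2.47,0
Q216A,AM2,124.9,23.7,0
F217A,AM1,101.8,7.45,0
F217A,AM2,99.0,12.0,0
A271L,AM1,118.8,13.2,0
A271L,AM2,118.8,20.6,0
I272A,AM1,115.9,15.6,0
I272A,AM2,64.1,23.5,0
A273L,AM1,112.3,11.6,0
A273L,AM2,107.7,6.74,0
R274A,AM1,98.1,17.3,0
R274A,AM2,107.2,14.4,0
S275A,AM1,77.3,10.1,0
S275A,AM2,113.0,25.3,0
L276A,AM1,73.8,10.2,0
L276A,AM2,110.3,21.7,0
Y277A,AM1,94.0,7.26,0
Y277A,AM2,132.4,23.0,0
Y278A,AM1,75.8,27.6,0
Y278A,AM2,154.1,27.1,0
N279A,AM1,97.0,6.30,0
N279A,AM2,96.8,17.0,0
D280A,AM1,155.8,68.9,0
D280A,AM2,126.1,16.8,0
N281A,AM1,108.1,2.90,0
N281A,AM2,119.9,2.97,0
C282A,AM1,64.9,16.8,0
C282A,AM2,100.7,11.7,0
W283A,AM1,107.7,11.9,0
W283A,AM2,100.4,13.4,0
I284A,AM1,67.1,8.80,0
I284A,AM2,107.6,26.2,0
S285A,AM1,86.1,20.2,0
S285A,AM2,124.7,31.6,0
S286A,AM1,93.2,12.9,0
S286A,AM2,104.7,15.0,0
D287A,AM1,77.4,13.4,0
D287A,AM2,107.3,7.33,0
T288A,AM1,94.8,23.5,0
T288A,AM2,90.0,7.14,0
H289A,AM1,93.1,16.2,0
H289A,AM2,95.7,12.9,0
L290A,AM1,102.5,2.45,0
L290A,AM2,98.6,7.36,0
L291A,AM1,103.5,7.54,0
L291A,AM2,130.8,10.3,0
Y292A,AM1,83.5,7.47,0
Y292A,AM2,176.5,40.6,0
I293A,AM1,99.2,1.44,0
I293A,AM2,107.9,12.5,0
I294A,AM1,103.2,14.7,0
I294A,AM2,102.8,29.8,0
F349A,AM1,98.5,11.3,0
F349A,AM2,93.9,22.5,0
V350A,AM1,104.2,8.06,0
V350A,AM2,106.5,33.4,0
L351A,AM1,9.75,3.17,1
L351A,AM2,21.9,12.3,1
I352A,AM1,68.9,10.2,1
I352A,AM2,121.2,13.7,0
P353A,AM1,94.2,8.95,0
P353A,AM2,104.0,23.8,0
W354A,AM1,85.9,9.30,0
W354A,AM2,103.7,24.0,0
R355A,AM1,114.7,13.0,0
R355A,AM2,86.5,11.8,0
P356A,AM1,101.3,3.59,0
P356A,AM2,87.6,13.3,0
E357A,AM1,17.2,4.85,1
E357A,AM2,15.1,9.97,1
G358A,AM1,108.2,7.72,0
G358A,AM2,85.7,9.81,0
K359A,AM1,99.6,2.63,0
K359A,AM2,76.3,11.9,0
I360A,AM1,85.8,3.81,0
I360A,AM2,82.5,7.48,0
A361L,AM1,102.2,3.45,0
A361L,AM2,83.1,8.75,0
E362A,AM1,103.8,6.14,0
E362A,AM2,75.4,4.93,0
E363A,AM1,103.0,2.74,0
E363A,AM2,75.6,4.22,0
V364A,AM1,94.0,2.74,0
V364A,AM2,100.5,12.5,0
Y365A,AM1,92.5,6.21,0
Y365A,AM2,121.3,24.5,0
D366A,AM1,107.5,4.33,0
D366A,AM2,103.1,19.4,0
Y367A,AM1,110.0,2.03,0
Y367A,AM2,106.2,16.4,0
I368A,AM1,90.8,15.2,0
I368A,AM2,118.6,24.7,0
M369A,AM1,82.8,13.9,0
M369A,AM2,108.2,25.1,0
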